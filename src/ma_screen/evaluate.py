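"""Detection evaluation: matching, rates, count accuracy and average precision.

Lesion detection has no meaningful true-negative count, so the battery is
precision/recall/F1 from one-to-one detection–ground-truth matching, a
per-image count accuracy at a relative tolerance (default 5%: an image passes
when its detected microaneurysm count is within 5% of the true count), and
average precision over confidence-ranked detections (single lesion class, so
mAP equals AP).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .types import Annotation, BoxDetection, CircleDetection, ValidationError
from .postprocess import box_iou


def detection_confidence(det) -> float:
    """Uniform confidence accessor: Hough score for circles, box confidence
    for boxes."""
    if isinstance(det, CircleDetection):
        return det.score
    return det.confidence


@dataclass(frozen=True)
class CenterDistanceCriterion:
    """Match when the center distance is at most ``max(base_px, gt radius)``."""

    base_px: float = 3.0

    def affinity(self, det, gt: Annotation) -> float | None:
        """Negated distance if the pair matches, else None (higher = better)."""
        if isinstance(det, CircleDetection):
            dx, dy = det.center_x - gt.center_x, det.center_y - gt.center_y
        else:
            x0, y0, x1, y1 = det.bbox
            dx = (x0 + x1) / 2.0 - gt.center_x
            dy = (y0 + y1) / 2.0 - gt.center_y
        dist = float(np.hypot(dx, dy))
        limit = max(self.base_px, gt.radius)
        return -dist if dist <= limit else None


@dataclass(frozen=True)
class IoUCriterion:
    """Match when box IoU with the ground-truth box is at least ``threshold``."""

    threshold: float = 0.5

    def affinity(self, det, gt: Annotation) -> float | None:
        if isinstance(det, CircleDetection):
            det_box = (
                det.center_x - det.radius, det.center_y - det.radius,
                det.center_x + det.radius, det.center_y + det.radius,
            )
        else:
            det_box = det.bbox
        iou = box_iou(det_box, gt.bbox)
        return iou if iou >= self.threshold else None


def default_criterion(dets: Sequence) -> CenterDistanceCriterion | IoUCriterion:
    if dets and isinstance(dets[0], BoxDetection):
        return IoUCriterion()
    return CenterDistanceCriterion()


@dataclass
class MatchResult:
    true_positives: int
    false_positives: int
    false_negatives: int
    pairs: list[tuple[int, int]] = field(default_factory=list)  # (det idx, gt idx)


def match_detections(dets: Sequence, gts: Sequence[Annotation], criterion=None) -> MatchResult:
    """Greedy one-to-one matching in descending detection confidence.

    Each detection, visited most-confident first, matches the best still
    unmatched ground truth satisfying the criterion (nearest center, or
    highest IoU); each side is used at most once.
    """
    criterion = criterion or default_criterion(dets)
    order = sorted(range(len(dets)), key=lambda i: (-detection_confidence(dets[i]), i))
    unmatched = set(range(len(gts)))
    pairs: list[tuple[int, int]] = []
    for di in order:
        best_gi, best_aff = None, None
        for gi in unmatched:
            aff = criterion.affinity(dets[di], gts[gi])
            if aff is not None and (best_aff is None or aff > best_aff):
                best_gi, best_aff = gi, aff
        if best_gi is not None:
            pairs.append((di, best_gi))
            unmatched.remove(best_gi)
    tp = len(pairs)
    return MatchResult(
        true_positives=tp,
        false_positives=len(dets) - tp,
        false_negatives=len(gts) - tp,
        pairs=sorted(pairs),
    )


def precision_recall_f1(m: MatchResult) -> tuple[float, float, float]:
    """``P = TP/(TP+FP)``, ``R = TP/(TP+FN)``, ``F1 = 2PR/(P+R)``; each
    degenerate 0/0 is defined as 0."""
    tp, fp, fn = m.true_positives, m.false_positives, m.false_negatives
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def count_tolerance_accuracy(
    pairs: Iterable[tuple[int, int]], tolerance: float = 0.05
) -> float:
    """Fraction of images whose detected count is within a relative tolerance.

    An image with true count ``t > 0`` passes iff ``|detected - t| <= tolerance * t``;
    with ``t = 0`` it passes iff the detected count is also 0.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValidationError("count_tolerance_accuracy needs at least one image")
    passed = 0
    for true_count, detected in pairs:
        if true_count < 0 or detected < 0:
            raise ValidationError(f"negative count in pair ({true_count}, {detected})")
        if true_count == 0:
            ok = detected == 0
        else:
            ok = abs(detected - true_count) <= tolerance * true_count
        passed += ok
    return passed / len(pairs)


def _ap_from_flags(flags: list[bool], n_gts: int) -> float:
    """All-points-interpolated area under the precision envelope."""
    tp = 0
    recalls, precisions = [0.0], [1.0]
    for rank, is_tp in enumerate(flags, start=1):
        tp += is_tp
        recalls.append(tp / n_gts)
        precisions.append(tp / rank)
    recalls = np.array(recalls)
    precisions = np.array(precisions)
    # precision envelope: running maximum from the right
    envelope = np.maximum.accumulate(precisions[::-1])[::-1]
    return float(np.sum(np.diff(recalls) * envelope[1:]))


def average_precision(dets: Sequence, gts: Sequence[Annotation], criterion=None) -> float | None:
    """AP of confidence-ranked detections against one image's ground truth.

    Detections are ranked by confidence descending; each is a true positive
    iff it matches a not-yet-claimed ground truth under the criterion.
    Returns None when there are no ground truths (AP undefined).
    """
    if not gts:
        return None
    per_image = [(list(dets), list(gts))]
    return pooled_average_precision(per_image, criterion)


def pooled_average_precision(
    per_image: Sequence[tuple[Sequence, Sequence[Annotation]]], criterion=None
) -> float | None:
    """AP over a dataset: all detections ranked together, matched per image."""
    n_gts = sum(len(gts) for _, gts in per_image)
    if n_gts == 0:
        return None
    ranked: list[tuple[float, int, int]] = []  # (-conf, image idx, det idx)
    for img_i, (dets, _) in enumerate(per_image):
        for di, det in enumerate(dets):
            ranked.append((-detection_confidence(det), img_i, di))
    ranked.sort()
    claimed: list[set[int]] = [set() for _ in per_image]
    flags: list[bool] = []
    for _, img_i, di in ranked:
        dets, gts = per_image[img_i]
        crit = criterion or default_criterion(list(dets))
        best_gi, best_aff = None, None
        for gi, gt in enumerate(gts):
            if gi in claimed[img_i]:
                continue
            aff = crit.affinity(dets[di], gt)
            if aff is not None and (best_aff is None or aff > best_aff):
                best_gi, best_aff = gi, aff
        if best_gi is not None:
            claimed[img_i].add(best_gi)
            flags.append(True)
        else:
            flags.append(False)
    if not flags:
        return 0.0
    return _ap_from_flags(flags, n_gts)


@dataclass
class PerImageResult:
    image_id: str
    true_count: int
    detected_count: int
    within_tolerance: bool


@dataclass
class EvaluationReport:
    """Aggregate metrics plus the per-image count table."""

    per_image: list[PerImageResult]
    sensitivity: float
    precision: float
    f1: float
    count_accuracy: float
    mean_average_precision: float | None
    tolerance: float = 0.05

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return path


def evaluate_dataset(
    items: Sequence[tuple[str, Sequence[Annotation], Sequence]],
    criterion=None,
    tolerance: float = 0.05,
) -> EvaluationReport:
    """Aggregate the full battery over ``(image_id, ground truths, detections)``
    triples.

    Matching counts are pooled over images for sensitivity/precision/F1;
    count accuracy uses the per-image microaneurysm counts; mAP pools all
    detections ranked by confidence.
    """
    if not items:
        raise ValidationError("evaluate_dataset needs at least one image")
    missing = [img_id for img_id, gts, _ in items if gts is None]
    if missing:
        raise ValidationError(f"missing annotations for images: {missing}")
    total = MatchResult(0, 0, 0)
    per_image: list[PerImageResult] = []
    count_pairs: list[tuple[int, int]] = []
    for img_id, gts, dets in items:
        m = match_detections(list(dets), list(gts), criterion)
        total.true_positives += m.true_positives
        total.false_positives += m.false_positives
        total.false_negatives += m.false_negatives
        pair = (len(gts), len(dets))
        count_pairs.append(pair)
        per_image.append(
            PerImageResult(
                image_id=img_id,
                true_count=pair[0],
                detected_count=pair[1],
                within_tolerance=count_tolerance_accuracy([pair], tolerance) == 1.0,
            )
        )
    precision, recall, f1 = precision_recall_f1(total)
    return EvaluationReport(
        per_image=per_image,
        sensitivity=recall,
        precision=precision,
        f1=f1,
        count_accuracy=count_tolerance_accuracy(count_pairs, tolerance),
        mean_average_precision=pooled_average_precision(
            [(list(dets), list(gts)) for _, gts, dets in items], criterion
        ),
        tolerance=tolerance,
    )
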