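"""Detection refinement: shape filtering, confidence filtering, NMS,
binary lesion masks, counting and overlays.

Two post-processing styles coexist. The classical circle path rejects false
positives by size and circularity of candidate regions and by the Hough
radius bounds; the box path (outputs of an external bounding-box detector)
is refined by confidence filtering and greedy non-maximum suppression.
Either path ends in a binary lesion mask, a microaneurysm count — the
clinically reported quantity — and an overlay for visual confirmation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import draw, measure

from .types import (
    MA,
    BinaryMap,
    BoxDetection,
    CircleDetection,
    FundusImage,
    ValidationError,
)


@dataclass
class ShapeFilterConfig:
    """Size/shape rejection bounds.

    Area bounds bracket the detectable radius regime (defaults: half a
    minimal disk to twice a maximal circle's loose bound);
    ``min_circularity`` is on the ``4*pi*area / perimeter^2`` scale, 1 for a
    perfect disk.
    """

    min_area: float = np.pi * 5**2 / 2
    max_area: float = 2 * np.pi * 25**2
    min_circularity: float = 0.6
    confidence_min: float = 0.25
    nms_iou: float = 0.45

    def __post_init__(self) -> None:
        if self.min_area > self.max_area:
            raise ValidationError("min_area must not exceed max_area")


@dataclass(frozen=True)
class RegionDetection:
    """A measurable connected region of a candidate map."""

    label: int
    area: float
    perimeter: float
    centroid: tuple[float, float]  # (x, y)
    bbox: tuple[int, int, int, int]  # half-open (x_min, y_min, x_max, y_max)


def regions_from_map(candidates: BinaryMap) -> list[RegionDetection]:
    """Connected components (8-connectivity) with area/perimeter measures."""
    labels = measure.label(candidates.values, connectivity=2)
    out = []
    for region in measure.regionprops(labels):
        y0, x0, y1, x1 = region.bbox
        cy, cx = region.centroid
        out.append(
            RegionDetection(
                label=region.label,
                area=float(region.area),
                perimeter=float(region.perimeter),
                centroid=(cx, cy),
                bbox=(x0, y0, x1, y1),
            )
        )
    return out


def _circularity(area: float, perimeter: float) -> float:
    if perimeter <= 0:
        return 1.0
    return min(4.0 * np.pi * area / perimeter**2, 1.0)


def shape_filter(regions, cfg: ShapeFilterConfig | None = None):
    """Keep regions (or circles) with lesion-like size and form.

    A region survives iff ``min_area <= area <= max_area`` and
    ``circularity >= min_circularity`` where circularity is
    ``4*pi*area/perimeter^2`` capped at 1. `CircleDetection` inputs use
    their ideal disk geometry (area ``pi r^2``, circularity 1), so only the
    size bounds apply to them.
    """
    cfg = cfg or ShapeFilterConfig()
    kept = []
    for det in regions:
        if isinstance(det, CircleDetection):
            area = np.pi * det.radius**2
            circ = 1.0
        else:
            area = det.area
            circ = _circularity(det.area, det.perimeter)
        if cfg.min_area <= area <= cfg.max_area and circ >= cfg.min_circularity:
            kept.append(det)
    return kept


def confidence_filter(dets: list[BoxDetection], min_conf: float) -> list[BoxDetection]:
    """Subset with confidence >= ``min_conf``, input order preserved."""
    return [d for d in dets if d.confidence >= min_conf]


def box_iou(a: tuple[float, float, float, float], b: tuple[float, float, float, float]) -> float:
    """Intersection over union of two half-open boxes."""
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    if inter == 0.0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def nms(dets: list[BoxDetection], iou_threshold: float = 0.45) -> list[BoxDetection]:
    """Greedy non-maximum suppression.

    Boxes are visited by confidence descending (ties: y_min, then x_min
    ascending) and accepted iff their IoU with every accepted box is at most
    ``iou_threshold``.
    """
    order = sorted(dets, key=lambda d: (-d.confidence, d.bbox[1], d.bbox[0]))
    accepted: list[BoxDetection] = []
    for det in order:
        if all(box_iou(det.bbox, a.bbox) <= iou_threshold for a in accepted):
            accepted.append(det)
    return accepted


def detections_to_mask(
    dets, shape: tuple[int, int]
) -> BinaryMap:
    """Union of filled circles / boxes as a binary lesion mask, clipped to
    the frame."""
    height, width = shape
    out = np.zeros((height, width), dtype=bool)
    for det in dets:
        if isinstance(det, CircleDetection):
            # filled disk = integer pixels within Euclidean distance r of the center
            x0 = max(det.center_x - det.radius, 0)
            x1 = min(det.center_x + det.radius + 1, width)
            y0 = max(det.center_y - det.radius, 0)
            y1 = min(det.center_y + det.radius + 1, height)
            if x0 >= x1 or y0 >= y1:
                continue
            yy, xx = np.ogrid[y0:y1, x0:x1]
            inside = (xx - det.center_x) ** 2 + (yy - det.center_y) ** 2 <= det.radius**2
            out[y0:y1, x0:x1] |= inside
        else:
            x0, y0, x1, y1 = det.bbox
            x0 = max(int(np.floor(x0)), 0)
            y0 = max(int(np.floor(y0)), 0)
            x1 = min(int(np.ceil(x1)), width)
            y1 = min(int(np.ceil(y1)), height)
            if x0 < x1 and y0 < y1:
                out[y0:y1, x0:x1] = True
    return BinaryMap(out)


def count_mas(dets) -> int:
    """Number of surviving microaneurysm detections.

    Circles are all MA candidates by construction; boxes are counted only if
    their class is MA.
    """
    n = 0
    for det in dets:
        if isinstance(det, BoxDetection) and det.lesion_class != MA:
            continue
        n += 1
    return n


_MARKER_RGB = (0, 255, 0)


def render_overlay(img: FundusImage, dets) -> np.ndarray:
    """Copy of the raster with detection outlines drawn in green."""
    out = img.pixels.copy()
    height, width = out.shape[:2]
    for det in dets:
        if isinstance(det, CircleDetection):
            rr, cc = draw.circle_perimeter(
                det.center_y, det.center_x, max(det.radius, 1), shape=(height, width)
            )
        else:
            x0, y0, x1, y1 = (int(round(v)) for v in det.bbox)
            rr, cc = draw.rectangle_perimeter(
                start=(max(y0, 0), max(x0, 0)),
                end=(min(y1, height) - 1, min(x1, width) - 1),
                shape=(height, width),
            )
        out[rr, cc] = _MARKER_RGB
    return out


def overlay(img: FundusImage, dets, out_path: str | Path) -> Path:
    """Write the original image with detections superimposed to ``out_path``."""
    from PIL import Image

    out_path = Path(out_path)
    rendered = render_overlay(img, dets)
    try:
        Image.fromarray(rendered, mode="RGB").save(out_path)
    except (OSError, ValueError) as exc:
        raise ValidationError(f"cannot write overlay to {out_path}: {exc}") from exc
    return out_path
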