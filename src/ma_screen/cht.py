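"""Circular Hough transform detection of microaneurysm candidates.

The classical detector: boundary pixels of the masked binary candidate map
vote for circle centers over a bounded radius range (default 5–25 px, the
microaneurysm size regime at 768x576 resolution). Accumulator peaks are
circle hypotheses; votes are normalised by the ideal perimeter count of each
radius so a single threshold serves all radii, and the normalised vote serves
as the detection confidence.

Circle rasterisation: the perimeter of radius ``r`` is the set of integer
offsets ``(dx, dy)`` with ``round(hypot(dx, dy)) == r``. This definition is
unambiguous and cheap to enumerate, and is shared by voting (stamp) and
normalisation (ideal count).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .mask import ExclusionMask, apply_mask, compute_exclusion_mask
from .preprocess import (
    adaptive_threshold,
    clahe,
    image_difference,
    median_filter,
    to_grayscale,
)
from .types import BinaryMap, CircleDetection, FundusImage, ValidationError


@dataclass
class ChtConfig:
    """Circle-Hough parameters.

    ``vote_threshold`` is the minimum fraction of a circle's ideal perimeter
    votes for a detection; ``min_center_distance`` is the minimum Euclidean
    distance between accepted centers (default ``r_min``: adjacent lesions
    are kept, concentric duplicates suppressed).
    """

    r_min: int = 5
    r_max: int = 25
    radius_step: int = 1
    vote_threshold: float = 0.45
    min_center_distance: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.r_min <= self.r_max:
            raise ValidationError(f"need 0 < r_min <= r_max, got {self.r_min}, {self.r_max}")
        if not 0.0 < self.vote_threshold <= 1.0:
            raise ValidationError(f"vote_threshold must be in (0, 1], got {self.vote_threshold}")
        if self.radius_step < 1:
            raise ValidationError("radius_step must be >= 1")
        if self.min_center_distance is None:
            self.min_center_distance = float(self.r_min)

    @property
    def radii(self) -> list[int]:
        return list(range(self.r_min, self.r_max + 1, self.radius_step))


@lru_cache(maxsize=64)
def circle_perimeter_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer offsets (dx, dy) with round(hypot(dx, dy)) == radius."""
    rng = np.arange(-radius, radius + 1)
    dx, dy = np.meshgrid(rng, rng)
    ring = np.rint(np.hypot(dx, dy)).astype(int) == radius
    return dx[ring].copy(), dy[ring].copy()


def edge_pixels(candidates: BinaryMap) -> np.ndarray:
    """Boundary pixels of the 1-regions: 1-pixels with a 0 (or out-of-frame)
    4-neighbour. Returns an (n, 2) array of (x, y) pairs, row-major order."""
    vals = candidates.values
    padded = np.pad(vals, 1, mode="constant", constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    boundary = vals & ~interior
    ys, xs = np.nonzero(boundary)
    return np.column_stack([xs, ys])


def hough_accumulate(
    edges: np.ndarray, config: ChtConfig, shape: tuple[int, int]
) -> np.ndarray:
    """Vote array of shape (n_radii, height, width), integer counts.

    Each edge pixel casts one vote per perimeter offset of each radius at
    the corresponding candidate center (centers outside the frame are
    dropped).
    """
    height, width = shape
    radii = config.radii
    acc = np.zeros((len(radii), height, width), dtype=np.int64)
    edges = np.asarray(edges)
    if edges.size == 0:
        return acc
    ex, ey = edges[:, 0], edges[:, 1]
    for i, r in enumerate(radii):
        dx, dy = circle_perimeter_offsets(r)
        cx = (ex[:, None] + dx[None, :]).ravel()
        cy = (ey[:, None] + dy[None, :]).ravel()
        ok = (cx >= 0) & (cx < width) & (cy >= 0) & (cy < height)
        flat = cy[ok] * width + cx[ok]
        acc[i] += np.bincount(flat, minlength=height * width).reshape(height, width)
    return acc


def detect_circles(accumulator: np.ndarray, config: ChtConfig) -> list[CircleDetection]:
    """Thresholded accumulator peaks, greedily separated by center distance.

    Scores are votes divided by the radius' ideal perimeter count, capped at
    1. Candidates with score >= ``vote_threshold`` are visited in order
    (score desc, then y, x, r asc — a fixed tie-break for determinism) and
    accepted iff their center is at least ``min_center_distance`` away from
    every previously accepted center.
    """
    radii = config.radii
    ideal = np.array([len(circle_perimeter_offsets(r)[0]) for r in radii], dtype=np.float64)
    scores = np.minimum(accumulator / ideal[:, None, None], 1.0)
    ri, ys, xs = np.nonzero(scores >= config.vote_threshold)
    if ri.size == 0:
        return []
    cand_scores = scores[ri, ys, xs]
    order = np.lexsort((ri, xs, ys, -cand_scores))
    accepted: list[CircleDetection] = []
    acc_xy: list[tuple[int, int]] = []
    min_d2 = float(config.min_center_distance) ** 2
    for idx in order:
        x, y = int(xs[idx]), int(ys[idx])
        if any((x - ax) ** 2 + (y - ay) ** 2 < min_d2 for ax, ay in acc_xy):
            continue
        accepted.append(
            CircleDetection(
                center_x=x, center_y=y, radius=int(radii[ri[idx]]),
                score=float(cand_scores[idx]),
            )
        )
        acc_xy.append((x, y))
    return accepted


def candidate_map(
    img: FundusImage,
    pipe_cfg: "object | None" = None,
) -> tuple[BinaryMap, ExclusionMask]:
    """Preprocess and mask an image into the binary candidate map.

    Pipeline order: grayscale blend -> median background -> difference ->
    CLAHE -> adaptive threshold (dark polarity) -> anatomy exclusion.
    ``pipe_cfg`` is a `ma_screen.io_cli.PipelineConfig`; defaults are used
    when omitted.
    """
    from .io_cli import PipelineConfig  # local import to avoid a cycle

    cfg = pipe_cfg or PipelineConfig()
    gray = to_grayscale(img)
    background = median_filter(gray, kernel_size=cfg.median_kernel)
    diff = image_difference(gray, background)
    enhanced = clahe(diff, clip_limit=cfg.clahe_clip, tiles=cfg.clahe_tiles)
    candidates = adaptive_threshold(
        enhanced, block_size=cfg.threshold_block, offset=cfg.threshold_offset,
        polarity="dark",
    )
    exclusion = compute_exclusion_mask(img, cfg.mask)
    return apply_mask(candidates, exclusion), exclusion


def cht_detect(
    img: FundusImage,
    pipe_cfg: "object | None" = None,
    cht_cfg: ChtConfig | None = None,
) -> list[CircleDetection]:
    """End-to-end classical detection on one image.

    Composition: preprocess -> mask -> edge pixels -> Hough accumulation ->
    peak detection; detections whose center falls inside the exclusion mask
    are dropped, so every returned circle lies in unmasked retina.
    """
    cht_cfg = cht_cfg or ChtConfig()
    candidates, exclusion = candidate_map(img, pipe_cfg)
    edges = edge_pixels(candidates)
    acc = hough_accumulate(edges, cht_cfg, candidates.values.shape)
    detections = detect_circles(acc, cht_cfg)
    return [
        d for d in detections if not exclusion.values[d.center_y, d.center_x]
    ]
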