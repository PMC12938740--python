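"""Suppression of non-lesion anatomy: optic disc, vessels, exudates, periphery.

These structures are the dominant false-positive sources for dark-blob
lesion detectors: vessel segments fragment into small dark pieces, the optic
disc rim and hard exudates create strong local contrast, and the field-of-view
(FOV) boundary is a circular edge that votes heavily in a circular Hough
transform. Each detector here is a deliberately simple suppression aid, not a
clinical-grade segmenter; all are replaceable behind `build_exclusion_mask`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .preprocess import to_grayscale
from .types import BinaryMap, FundusImage, IntensityMap, ValidationError

COMPONENT_NAMES = ("optic_disc", "vessel", "exudate", "periphery")


@dataclass
class ExclusionMask:
    """Binary raster of excluded pixels with per-component provenance.

    Invariant: the union of the component masks equals ``values``.
    """

    values: np.ndarray
    components: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        for name, comp in self.components.items():
            if comp.shape != self.values.shape:
                raise ValidationError(f"component {name!r} shape mismatch")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class MaskConfig:
    """Parameters of the anatomy detectors and their dilation margins (px)."""

    fov_threshold: int = 20
    disc_radius_range: tuple[int, int] = (20, 80)
    disc_min_prominence: float = 30.0
    vessel_tophat_radius: int = 7
    vessel_threshold: float = 10.0
    vessel_min_elongation: float = 3.0
    vessel_min_area: int = 30
    exudate_percentile: float = 99.0
    exudate_min_contrast: float = 40.0
    margin_disc: int = 10
    margin_vessel: int = 2
    margin_exudate: int = 3
    fov_erosion: int = 5


def detect_fov(img: FundusImage, threshold: int = 20) -> BinaryMap:
    """Field of view: largest bright connected region of the red channel.

    The red channel is saturated inside the illuminated retina and near zero
    on the dark surround, making it the most reliable FOV cue. The largest
    connected component above ``threshold`` is kept and hole-filled.
    """
    red = img.pixels[:, :, 0]
    bright = red > threshold
    if not bright.any():
        raise ValidationError("empty field of view: no pixel above the FOV threshold")
    labels, n = ndimage.label(bright)
    if n > 1:
        sizes = ndimage.sum_labels(bright, labels, index=np.arange(1, n + 1))
        keep = 1 + int(np.argmax(sizes))
        bright = labels == keep
    bright = ndimage.binary_fill_holes(bright)
    return BinaryMap(bright)


def detect_optic_disc(
    img: FundusImage,
    fov: BinaryMap,
    expected_radius_range: tuple[int, int] = (20, 80),
    min_prominence: float = 30.0,
) -> tuple[tuple[int, int], int] | None:
    """Locate the optic disc as the brightest compact region inside the FOV.

    The grayscale image is smoothed with a kernel on the scale of the disc;
    the global maximum inside the (eroded) FOV is the disc center candidate.
    If the peak does not rise at least ``min_prominence`` gray levels above
    the FOV median the scene is taken to contain no disc and ``None`` is
    returned. The radius is estimated from the area of the bright region
    around the peak and clipped into ``expected_radius_range``.

    Returns ``((center_x, center_y), radius)`` or ``None``.
    """
    r_lo, r_hi = expected_radius_range
    gray = to_grayscale(img).values.astype(np.float64)
    fov_vals = fov.values
    sigma = max(r_lo / 2.0, 2.0)
    smooth = ndimage.gaussian_filter(gray, sigma=sigma, mode="reflect")
    interior = ndimage.binary_erosion(fov_vals, iterations=3)
    if not interior.any():
        interior = fov_vals
    masked = np.where(interior, smooth, -np.inf)
    peak_flat = int(np.argmax(masked))
    cy, cx = np.unravel_index(peak_flat, masked.shape)
    background = float(np.median(gray[fov_vals]))
    if masked[cy, cx] < background + min_prominence:
        return None
    # region above the half-prominence level, restricted to the peak's component
    level = background + 0.5 * (masked[cy, cx] - background)
    bright = (smooth >= level) & fov_vals
    labels, _ = ndimage.label(bright)
    region = labels == labels[cy, cx]
    area = int(region.sum())
    radius = int(np.clip(round(np.sqrt(area / np.pi)), r_lo, r_hi))
    # refine the center to the region centroid for stability
    ys, xs = np.nonzero(region)
    return (int(round(xs.mean())), int(round(ys.mean()))), radius


def detect_vessels(
    gray: IntensityMap,
    fov: BinaryMap | None = None,
    tophat_radius: int = 7,
    threshold: float = 10.0,
    min_elongation: float = 3.0,
    min_area: int = 30,
) -> BinaryMap:
    """Dark curvilinear structure map via black top-hat + elongation filtering.

    The black top-hat (closing residue) with a disc structuring element
    responds to any structure darker than its surroundings and thinner than
    the disc — vessels, but also microaneurysms. Components are therefore
    filtered by elongation, measured as ``perimeter^2 / (4*pi*area)`` (the
    inverse of circularity, 1 for a disc, large for thin or branched
    shapes): only components with elongation >= ``min_elongation`` and area
    >= ``min_area`` are kept, so small round lesions are not swallowed.
    """
    vals = gray.values.astype(np.float64)
    selem = morphology.disk(tophat_radius)
    bottom = morphology.closing(vals, selem) - vals
    candidates = bottom > threshold
    if fov is not None:
        candidates &= fov.values
    out = np.zeros_like(candidates)
    labels = measure.label(candidates, connectivity=2)
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        perimeter = max(region.perimeter, 1.0)
        elongation = perimeter**2 / (4.0 * np.pi * region.area)
        if elongation >= min_elongation:
            out[labels == region.label] = True
    return BinaryMap(out)


def detect_exudates(
    img: FundusImage,
    fov: BinaryMap,
    disc: tuple[tuple[int, int], int] | None = None,
    percentile: float = 99.0,
    min_contrast: float = 40.0,
    dilation: int = 3,
) -> BinaryMap:
    """Bright-lesion map: high-percentile bright pixels well above background.

    The threshold is the larger of the given intensity ``percentile`` over
    FOV pixels (optic-disc region excluded) and ``FOV median +
    min_contrast``; the contrast floor keeps exudate-free images from
    always flagging the top percentile of plain background. The optic-disc
    circle is removed and the result dilated by ``dilation`` px.
    """
    gray = to_grayscale(img).values.astype(np.float64)
    sample = fov.values.copy()
    disc_region = np.zeros_like(sample)
    if disc is not None:
        (dcx, dcy), dr = disc
        yy, xx = np.ogrid[: sample.shape[0], : sample.shape[1]]
        disc_region = (xx - dcx) ** 2 + (yy - dcy) ** 2 <= dr**2
        sample &= ~disc_region
    if not sample.any():
        return BinaryMap(np.zeros_like(fov.values))
    vals = gray[sample]
    if percentile >= 100.0:
        return BinaryMap(np.zeros_like(fov.values))
    thr = max(float(np.percentile(vals, percentile)), float(np.median(vals)) + min_contrast)
    bright = (gray > thr) & sample
    if dilation > 0 and bright.any():
        bright = ndimage.binary_dilation(bright, structure=morphology.disk(dilation))
        bright &= fov.values
    return BinaryMap(bright)


def _dilate(maskarr: np.ndarray, margin: int) -> np.ndarray:
    if margin <= 0 or not maskarr.any():
        return maskarr.astype(bool)
    return ndimage.binary_dilation(maskarr, structure=morphology.disk(margin))


def build_exclusion_mask(
    fov: BinaryMap,
    disc: tuple[tuple[int, int], int] | None = None,
    vessels: BinaryMap | None = None,
    exudates: BinaryMap | None = None,
    margins: MaskConfig | None = None,
) -> ExclusionMask:
    """Union the dilated anatomy masks with the FOV-erosion periphery.

    ``mask = dilate(disc) ∪ dilate(vessels) ∪ dilate(exudates)
    ∪ complement(erode(fov))``; per-component provenance is retained.
    Larger margins can only grow the mask (monotonicity).
    """
    cfg = margins or MaskConfig()
    shape = fov.values.shape
    components: dict[str, np.ndarray] = {}

    disc_mask = np.zeros(shape, dtype=bool)
    if disc is not None:
        (cx, cy), r = disc
        yy, xx = np.ogrid[: shape[0], : shape[1]]
        disc_mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= (r + cfg.margin_disc) ** 2
    components["optic_disc"] = disc_mask

    vessel_mask = np.zeros(shape, dtype=bool)
    if vessels is not None:
        if vessels.values.shape != shape:
            raise ValidationError("vessel mask dimensions do not match FOV")
        vessel_mask = _dilate(vessels.values, cfg.margin_vessel)
    components["vessel"] = vessel_mask

    exudate_mask = np.zeros(shape, dtype=bool)
    if exudates is not None:
        if exudates.values.shape != shape:
            raise ValidationError("exudate mask dimensions do not match FOV")
        exudate_mask = _dilate(exudates.values, cfg.margin_exudate)
    components["exudate"] = exudate_mask

    interior = fov.values
    if cfg.fov_erosion > 0:
        interior = ndimage.binary_erosion(
            fov.values, structure=morphology.disk(cfg.fov_erosion)
        )
    components["periphery"] = ~interior

    union = np.zeros(shape, dtype=bool)
    for comp in components.values():
        union |= comp
    return ExclusionMask(union, components)


def apply_mask(candidates: BinaryMap, mask: ExclusionMask) -> BinaryMap:
    """Zero candidate pixels that fall inside the exclusion mask."""
    if candidates.values.shape != mask.values.shape:
        raise ValidationError(
            f"dimension mismatch: {candidates.values.shape} vs {mask.values.shape}"
        )
    return BinaryMap(candidates.values & ~mask.values)


def compute_exclusion_mask(img: FundusImage, cfg: MaskConfig | None = None) -> ExclusionMask:
    """Run all anatomy detectors on an image and assemble the exclusion mask."""
    cfg = cfg or MaskConfig()
    fov = detect_fov(img, threshold=cfg.fov_threshold)
    disc = detect_optic_disc(
        img, fov, expected_radius_range=cfg.disc_radius_range,
        min_prominence=cfg.disc_min_prominence,
    )
    gray = to_grayscale(img)
    vessels = detect_vessels(
        gray, fov,
        tophat_radius=cfg.vessel_tophat_radius,
        threshold=cfg.vessel_threshold,
        min_elongation=cfg.vessel_min_elongation,
        min_area=cfg.vessel_min_area,
    )
    # dilation deferred to build_exclusion_mask so the margin is applied once
    exudates = detect_exudates(
        img, fov, disc,
        percentile=cfg.exudate_percentile,
        min_contrast=cfg.exudate_min_contrast,
        dilation=0,
    )
    return build_exclusion_mask(fov, disc, vessels, exudates, margins=cfg)
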