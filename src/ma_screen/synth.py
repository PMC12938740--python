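"""Synthetic annotated fundus scenes for desk-scale testing of the pipeline.

A rendered scene emulates the statistical structure a fundus photograph
presents to a classical lesion detector: a circular illuminated field of view
(FOV) on a dark background, a radial illumination falloff, a bright optic
disc, a dark branching vessel tree grown by a recursive random walk, bright
exudate blobs, and sparse small dark reddish microaneurysms (the lesions of
interest, radius 2–25 px at the working resolution of 768x576). It is *not*
photorealistic — no texture, haemorrhages or acquisition artefacts — but every
structure the masking and detection stages must handle is present, with exact
ground truth.

Microaneurysms are rendered by default with a radial cosine contrast profile
(full contrast at the center, fading to zero at the rim) rather than hard
disks: hard-edged disks make circle detection trivially easy, soft profiles
exercise the thresholding realistically. All randomness flows from a single
integer seed; identical ``(spec, seed)`` renders are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .types import (
    EXUDATE,
    MA,
    OPTIC_DISC,
    Annotation,
    AnnotationSet,
    FundusImage,
    ValidationError,
    circle_bbox,
)

# background chromaticity of the illuminated retina (8-bit RGB)
_RETINA_RGB = (186.0, 98.0, 38.0)
_OUTSIDE_RGB = (6.0, 3.0, 2.0)

MA_RADIUS_BOUNDS = (2.0, 25.0)


@dataclass(frozen=True)
class OpticDiscSpec:
    center: tuple[float, float] = (560.0, 288.0)
    radius: float = 40.0
    brightness: float = 80.0  # additive offset, gray levels


@dataclass(frozen=True)
class VesselTreeSpec:
    n_root_branches: int = 5
    branch_decay: float = 0.75  # child width ratio per branching, in (0,1)
    width_px: float = 4.0
    darkness: float = 45.0  # subtractive offset, gray levels


@dataclass(frozen=True)
class LesionSpec:
    """A planted circular lesion: dark (MA) or bright (exudate)."""

    center: tuple[float, float]
    radius: float
    contrast: float  # gray-level offset; darkening for MAs, brightening for exudates


@dataclass
class SceneSpec:
    """Full description of one synthetic scene; `render_fundus` is a pure
    deterministic function of it."""

    width: int = 768
    height: int = 576
    fov_center: tuple[float, float] = (384.0, 288.0)
    fov_radius: float = 260.0
    illumination_gradient: float = 0.15  # quadratic radial falloff amplitude, [0, 1]
    optic_disc: OpticDiscSpec | None = field(default_factory=OpticDiscSpec)
    vessel_tree: VesselTreeSpec | None = field(default_factory=VesselTreeSpec)
    exudates: list[LesionSpec] = field(default_factory=list)
    mas: list[LesionSpec] = field(default_factory=list)
    noise_sigma: float = 2.0  # gray levels, i.i.d. gaussian per channel
    seed: int = 0
    soft_profile: bool = True  # cosine MA profile; False renders hard disks
    non_overlapping: bool = False  # enforce pairwise disjoint MA disks

    def validate(self) -> None:
        fx, fy = self.fov_center
        if not 0.0 <= self.illumination_gradient <= 1.0:
            raise ValidationError("illumination_gradient must be in [0, 1]")
        for kind, lesions in ((MA, self.mas), (EXUDATE, self.exudates)):
            for i, les in enumerate(lesions):
                dx, dy = les.center[0] - fx, les.center[1] - fy
                if np.hypot(dx, dy) > self.fov_radius:
                    raise ValidationError(
                        f"{kind} lesion #{i} at {les.center} lies outside the "
                        f"field-of-view circle (center {self.fov_center}, "
                        f"radius {self.fov_radius})"
                    )
        for i, ma in enumerate(self.mas):
            if not MA_RADIUS_BOUNDS[0] <= ma.radius <= MA_RADIUS_BOUNDS[1]:
                raise ValidationError(
                    f"MA lesion #{i} radius {ma.radius} outside {MA_RADIUS_BOUNDS}"
                )
        if self.non_overlapping:
            for i in range(len(self.mas)):
                for j in range(i + 1, len(self.mas)):
                    a, b = self.mas[i], self.mas[j]
                    d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                    if d < a.radius + b.radius:
                        raise ValidationError(
                            f"MA lesions #{i} and #{j} overlap (distance {d:.1f})"
                        )


def _vessel_rng(spec: SceneSpec) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed) % (2**31), 1])


def _noise_rng(spec: SceneSpec) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed) % (2**31), 2])


def vessel_paths(spec: SceneSpec) -> list[tuple[np.ndarray, float]]:
    """Centerline polylines of the vessel tree, as ``(points, width)`` pairs.

    Branches grow by a recursive random walk from the optic disc (or the FOV
    center when no disc is present) toward the periphery, forking with
    probability per step; child branches shrink in width by ``branch_decay``.
    Deterministic given the spec seed, and shared between rendering and the
    scene sampler (which places lesions clear of the vessels).
    """
    if spec.vessel_tree is None:
        return []
    vt = spec.vessel_tree
    rng = _vessel_rng(spec)
    ox, oy = spec.optic_disc.center if spec.optic_disc else spec.fov_center
    fx, fy = spec.fov_center
    paths: list[tuple[np.ndarray, float]] = []

    def grow(x: float, y: float, heading: float, width: float, length: float, depth: int) -> None:
        pts = [(x, y)]
        step = 4.0
        n_steps = int(length / step)
        for _ in range(n_steps):
            heading += rng.normal(0.0, 0.18)
            x += step * np.cos(heading)
            y += step * np.sin(heading)
            if np.hypot(x - fx, y - fy) > spec.fov_radius - 2:
                break
            pts.append((x, y))
            if depth < 3 and rng.random() < 0.03:
                grow(
                    x, y, heading + rng.choice([-1.0, 1.0]) * rng.uniform(0.4, 0.9),
                    width * vt.branch_decay, length * 0.6, depth + 1,
                )
        if len(pts) > 1:
            paths.append((np.array(pts), width))

    for k in range(vt.n_root_branches):
        angle = 2 * np.pi * k / vt.n_root_branches + rng.uniform(-0.3, 0.3)
        start_r = spec.optic_disc.radius if spec.optic_disc else 5.0
        x0 = ox + start_r * np.cos(angle)
        y0 = oy + start_r * np.sin(angle)
        grow(x0, y0, angle, vt.width_px, length=2.2 * spec.fov_radius, depth=0)
    return paths


def _stamp_soft_disk(
    field_arr: np.ndarray, cx: float, cy: float, radius: float, amount: float,
    soft: bool,
) -> None:
    """Add ``amount`` (signed) inside a disk, optionally cosine-profiled."""
    h, w = field_arr.shape
    x0 = max(int(np.floor(cx - radius)) - 1, 0)
    x1 = min(int(np.ceil(cx + radius)) + 2, w)
    y0 = max(int(np.floor(cy - radius)) - 1, 0)
    y1 = min(int(np.ceil(cy + radius)) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xx - cx, yy - cy)
    if soft == "plateau":
        # flat core with a cosine rim ramp: emulates sharp-edged structures
        # (the optic disc) without aliasing artefacts
        core = 0.75 * radius
        ramp = 0.5 * (1.0 + np.cos(np.pi * (d - core) / (radius - core)))
        profile = np.where(d <= core, 1.0, np.where(d <= radius, ramp, 0.0))
    elif soft:
        profile = np.where(d <= radius, 0.5 * (1.0 + np.cos(np.pi * d / radius)), 0.0)
    else:
        profile = (d <= radius).astype(float)
    field_arr[y0:y1, x0:x1] += amount * profile


def _stamp_polyline(
    field_arr: np.ndarray, pts: np.ndarray, width: float, amount: float
) -> None:
    """Add ``amount`` along a polyline drawn with round caps of ``width`` px."""
    radius = max(width / 2.0, 0.6)
    h, w = field_arr.shape
    # dense samples along segments so consecutive stamps overlap
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        seg = np.hypot(x1 - x0, y1 - y0)
        n = max(int(seg / max(radius * 0.7, 0.7)) + 1, 2)
        for t in np.linspace(0.0, 1.0, n):
            cx, cy = x0 + t * (x1 - x0), y0 + t * (y1 - y0)
            ix0 = max(int(np.floor(cx - radius)), 0)
            ix1 = min(int(np.ceil(cx + radius)) + 1, w)
            iy0 = max(int(np.floor(cy - radius)), 0)
            iy1 = min(int(np.ceil(cy + radius)) + 1, h)
            if ix0 >= ix1 or iy0 >= iy1:
                continue
            yy, xx = np.mgrid[iy0:iy1, ix0:ix1]
            inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
            patch = field_arr[iy0:iy1, ix0:ix1]
            # extremum blend so overlapping stamps do not stack darkness
            blend = np.minimum if amount < 0 else np.maximum
            blend(patch, np.where(inside, amount, patch), out=patch)


def annotations_for(spec: SceneSpec) -> AnnotationSet:
    """Ground-truth annotation set listing exactly the planted lesions."""
    entries: list[Annotation] = []
    for les in spec.mas:
        cx, cy = les.center
        entries.append(
            Annotation(MA, cx, cy, les.radius,
                       circle_bbox(cx, cy, les.radius, spec.width, spec.height))
        )
    for les in spec.exudates:
        cx, cy = les.center
        entries.append(
            Annotation(EXUDATE, cx, cy, les.radius,
                       circle_bbox(cx, cy, les.radius, spec.width, spec.height))
        )
    if spec.optic_disc is not None:
        cx, cy = spec.optic_disc.center
        entries.append(
            Annotation(OPTIC_DISC, cx, cy, spec.optic_disc.radius,
                       circle_bbox(cx, cy, spec.optic_disc.radius,
                                   spec.width, spec.height))
        )
    return AnnotationSet(entries, spec.width, spec.height)


def render_fundus(spec: SceneSpec) -> tuple[FundusImage, AnnotationSet]:
    """Render a scene to an 8-bit RGB raster plus its exact ground truth.

    Compositing order: illuminated background, vessels, exudates, optic
    disc, microaneurysms, then gaussian sensor noise; the raster is clipped
    to [0, 255] at the end. Bit-identical for identical ``(spec, seed)``.
    """
    spec.validate()
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w]
    fx, fy = spec.fov_center
    dist = np.hypot(xx - fx, yy - fy)
    fov = dist <= spec.fov_radius

    # radial quadratic illumination falloff inside the FOV
    illum = 1.0 - spec.illumination_gradient * (dist / spec.fov_radius) ** 2
    channels = []
    for inside_level, outside_level in zip(_RETINA_RGB, _OUTSIDE_RGB):
        chan = np.where(fov, inside_level * illum, outside_level)
        channels.append(chan.astype(np.float64))
    r_chan, g_chan, b_chan = channels

    # vessels: dark curvilinear tree (drawn as a darkness field, max-blended)
    if spec.vessel_tree is not None:
        dark = np.zeros((h, w))
        for pts, width in vessel_paths(spec):
            _stamp_polyline(dark, pts, width, -spec.vessel_tree.darkness)
        r_chan += dark * 0.7
        g_chan += dark

    # exudates: bright yellowish blobs (strong in R and G)
    for les in spec.exudates:
        _stamp_soft_disk(r_chan, *les.center, les.radius, les.contrast, soft=True)
        _stamp_soft_disk(g_chan, *les.center, les.radius, les.contrast, soft=True)

    # optic disc: bright compact region, soft rim
    if spec.optic_disc is not None:
        od = spec.optic_disc
        for chan, scale in ((r_chan, 1.0), (g_chan, 1.0), (b_chan, 0.6)):
            _stamp_soft_disk(chan, *od.center, od.radius * 1.1, scale * od.brightness,
                             soft="plateau")

    # microaneurysms: small dark reddish disks (darkest in green)
    for les in spec.mas:
        _stamp_soft_disk(g_chan, *les.center, les.radius, -les.contrast,
                         soft=spec.soft_profile)
        _stamp_soft_disk(r_chan, *les.center, les.radius, -0.6 * les.contrast,
                         soft=spec.soft_profile)

    stack = np.stack([r_chan, g_chan, b_chan], axis=-1)
    if spec.noise_sigma > 0:
        stack = stack + _noise_rng(spec).normal(0.0, spec.noise_sigma, stack.shape)
    pixels = np.clip(np.rint(stack), 0, 255).astype(np.uint8)
    return FundusImage(pixels, fov_mask=fov), annotations_for(spec)


@dataclass
class SceneSampler:
    """Uniform sampling ranges for random scenes (the study conditions).

    Defaults keep microaneurysm pixels well under 1% of the FOV — the severe
    class imbalance characteristic of real screening data.
    """

    ma_count_range: tuple[int, int] = (3, 10)
    ma_radius_range: tuple[float, float] = (3.0, 12.0)
    ma_contrast_range: tuple[float, float] = (40.0, 80.0)
    exudate_count_range: tuple[int, int] = (0, 3)
    exudate_radius_range: tuple[float, float] = (6.0, 14.0)
    exudate_contrast_range: tuple[float, float] = (60.0, 100.0)
    noise_sigma: float = 2.0
    off_anatomy_margin: float = 10.0  # min clearance from vessels/disc, px
    edge_margin: float = 15.0  # min clearance inside the FOV rim, px
    with_optic_disc: bool = True
    with_vessels: bool = True
    non_overlapping: bool = True
    max_retries: int = 400

    def __post_init__(self) -> None:
        for name in ("ma_count_range", "ma_radius_range", "ma_contrast_range",
                     "exudate_count_range", "exudate_radius_range",
                     "exudate_contrast_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name} is empty: {lo} > {hi}")


def high_contrast_sampler() -> "SceneSampler":
    """Conditions of the planted-lesion recovery study: microaneurysms of
    radius 6–12 px at strong contrast, placed clear of anatomy and the FOV
    rim. Used by the recovery tests and the acceptance run."""
    return SceneSampler(ma_radius_range=(6.0, 12.0), ma_contrast_range=(60.0, 90.0))


def _min_dist_to_paths(x: float, y: float, paths) -> float:
    best = np.inf
    for pts, width in paths:
        d = np.hypot(pts[:, 0] - x, pts[:, 1] - y) - width / 2.0
        best = min(best, float(d.min()))
    return best


def sample_scene(params: SceneSampler | None = None, seed: int = 0) -> SceneSpec:
    """Draw a reproducible random `SceneSpec` from the sampler's ranges.

    Lesions are placed by rejection sampling: inside the FOV (clear of the
    rim by ``edge_margin``), clear of the optic disc and the vessel
    centerlines by ``off_anatomy_margin``, and (by default) pairwise
    non-overlapping. Placement failing after ``max_retries`` draws raises a
    validation error — the requested density does not fit the FOV.
    """
    params = params or SceneSampler()
    seed = int(seed) % (2**31)
    rng = np.random.default_rng([seed, 0])

    spec = SceneSpec(
        optic_disc=OpticDiscSpec() if params.with_optic_disc else None,
        vessel_tree=VesselTreeSpec() if params.with_vessels else None,
        noise_sigma=params.noise_sigma,
        seed=seed,
        non_overlapping=params.non_overlapping,
    )
    paths = vessel_paths(spec)
    fx, fy = spec.fov_center

    def place(radius: float, clearance: float, placed: list[LesionSpec]) -> tuple[float, float]:
        limit = spec.fov_radius - params.edge_margin - radius
        for _ in range(params.max_retries):
            ang = rng.uniform(0.0, 2 * np.pi)
            rad = limit * np.sqrt(rng.uniform())
            x, y = fx + rad * np.cos(ang), fy + rad * np.sin(ang)
            if spec.optic_disc is not None:
                od = spec.optic_disc
                if np.hypot(x - od.center[0], y - od.center[1]) < od.radius + radius + clearance:
                    continue
            if paths and _min_dist_to_paths(x, y, paths) < radius + clearance:
                continue
            if params.non_overlapping and any(
                np.hypot(x - p.center[0], y - p.center[1]) < radius + p.radius + 2.0
                for p in placed
            ):
                continue
            return x, y
        raise ValidationError(
            f"could not place a lesion of radius {radius:.1f} after "
            f"{params.max_retries} retries — density too high for the FOV"
        )

    n_ma = int(rng.integers(params.ma_count_range[0], params.ma_count_range[1] + 1))
    mas: list[LesionSpec] = []
    for _ in range(n_ma):
        radius = float(rng.uniform(*params.ma_radius_range))
        contrast = float(rng.uniform(*params.ma_contrast_range))
        x, y = place(radius, params.off_anatomy_margin, mas)
        mas.append(LesionSpec((round(x, 1), round(y, 1)), round(radius, 1), round(contrast, 1)))

    n_ex = int(rng.integers(params.exudate_count_range[0], params.exudate_count_range[1] + 1))
    exudates: list[LesionSpec] = []
    for _ in range(n_ex):
        radius = float(rng.uniform(*params.exudate_radius_range))
        contrast = float(rng.uniform(*params.exudate_contrast_range))
        x, y = place(radius, params.off_anatomy_margin, exudates + mas)
        exudates.append(
            LesionSpec((round(x, 1), round(y, 1)), round(radius, 1), round(contrast, 1))
        )

    spec.mas = mas
    spec.exudates = exudates
    spec.validate()
    return spec


def flip_augment(
    image: FundusImage,
    ann: AnnotationSet,
    mode: Literal["horizontal", "vertical"],
) -> tuple[FundusImage, AnnotationSet]:
    """Mirror the raster and remap annotations along the stated axis.

    Centers are remapped on the pixel grid (``x' = width - 1 - x`` for a
    horizontal flip), boxes by mirroring the half-open interval
    (``[x_min, x_max) -> [width - x_max, width - x_min)``); radii are
    unchanged. Applying the same flip twice is the identity.
    """
    if mode not in ("horizontal", "vertical"):
        raise ValidationError(f"mode must be 'horizontal' or 'vertical', got {mode!r}")
    w, h = ann.image_width or image.width, ann.image_height or image.height
    horizontal = mode == "horizontal"
    axis = 1 if horizontal else 0
    pixels = np.flip(image.pixels, axis=axis).copy()
    fov = np.flip(image.fov_mask, axis=axis).copy() if image.fov_mask is not None else None
    entries = []
    for e in ann.entries:
        x_min, y_min, x_max, y_max = e.bbox
        if horizontal:
            cx, cy = (w - 1) - e.center_x, e.center_y
            bbox = (w - x_max, y_min, w - x_min, y_max)
        else:
            cx, cy = e.center_x, (h - 1) - e.center_y
            bbox = (x_min, h - y_max, x_max, h - y_min)
        entries.append(Annotation(e.lesion_class, cx, cy, e.radius, bbox))
    return (
        FundusImage(pixels, fov_mask=fov),
        AnnotationSet(entries, ann.image_width, ann.image_height),
    )
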