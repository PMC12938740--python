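"""Shared raster and annotation containers used across the pipeline.

Coordinate conventions (used everywhere in this package):

* 0-based pixel indices; ``x`` is the column (increasing rightward) and
  ``y`` the row (increasing downward).
* Bounding boxes are half-open: ``(x_min, y_min, x_max, y_max)`` covers
  columns ``x_min <= x < x_max`` and rows ``y_min <= y < y_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

MA = "MA"
EXUDATE = "exudate"
OPTIC_DISC = "optic_disc"
LESION_CLASSES = (MA, EXUDATE, OPTIC_DISC)

#: integer id used by the YOLO text label format, per lesion class
YOLO_CLASS_IDS = {MA: 0, EXUDATE: 1, OPTIC_DISC: 2}
YOLO_CLASS_NAMES = {v: k for k, v in YOLO_CLASS_IDS.items()}


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


@dataclass
class FundusImage:
    """8-bit RGB colour fundus raster with an optional field-of-view mask."""

    pixels: np.ndarray
    fov_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValidationError(
                f"FundusImage requires an (H, W, 3) raster, got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            raise ValidationError(f"FundusImage requires uint8 pixels, got {self.pixels.dtype}")
        if self.fov_mask is not None:
            self.fov_mask = np.asarray(self.fov_mask, dtype=bool)
            if self.fov_mask.shape != self.pixels.shape[:2]:
                raise ValidationError(
                    "fov_mask shape "
                    f"{self.fov_mask.shape} does not match raster {self.pixels.shape[:2]}"
                )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class IntensityMap:
    """Single-channel raster with a recorded value domain (default 8-bit)."""

    values: np.ndarray
    domain: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError(f"IntensityMap requires a 2-D raster, got {self.values.shape}")
        lo, hi = self.domain
        if self.values.size and (self.values.min() < lo or self.values.max() > hi):
            raise ValidationError(
                f"IntensityMap values outside declared domain [{lo}, {hi}]"
            )

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class BinaryMap:
    """Strictly two-valued {0, 1} raster, stored as bool."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise ValidationError(f"BinaryMap requires a 2-D raster, got {arr.shape}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.isin(uniq, (0, 1)).all():
                raise ValidationError("BinaryMap values must be in {0, 1}")
            arr = arr.astype(bool)
        self.values = arr

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class Annotation:
    """One ground-truth lesion: class, circle geometry and a tight box."""

    lesion_class: str
    center_x: float
    center_y: float
    radius: float
    bbox: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.lesion_class not in LESION_CLASSES:
            raise ValidationError(f"unknown lesion class {self.lesion_class!r}")
        # canonicalise to a 1e-6 px grid: keeps coordinate remappings such as
        # mirror flips exactly involutive despite float rounding
        self.center_x = round(float(self.center_x), 6)
        self.center_y = round(float(self.center_y), 6)
        self.radius = round(float(self.radius), 6)
        self.bbox = tuple(round(float(v), 6) for v in self.bbox)
        x_min, y_min, x_max, y_max = self.bbox
        if not (x_min < x_max and y_min < y_max):
            raise ValidationError(f"degenerate bbox {self.bbox}")


def circle_bbox(
    cx: float, cy: float, radius: float, width: int, height: int
) -> tuple[float, float, float, float]:
    """Tight half-open box around a circle, clipped to the image frame."""
    return (
        max(cx - radius, 0.0),
        max(cy - radius, 0.0),
        min(cx + radius, float(width)),
        min(cy + radius, float(height)),
    )


@dataclass
class AnnotationSet:
    """Ground-truth lesions for one image."""

    entries: list[Annotation] = field(default_factory=list)
    image_width: int = 0
    image_height: int = 0

    def of_class(self, lesion_class: str) -> list[Annotation]:
        return [e for e in self.entries if e.lesion_class == lesion_class]

    @property
    def ma_entries(self) -> list[Annotation]:
        return self.of_class(MA)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class CircleDetection:
    """Circle-Hough candidate: center, radius and a normalised vote score."""

    center_x: int
    center_y: int
    radius: int
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError(f"score {self.score} outside [0, 1]")


@dataclass(frozen=True)
class BoxDetection:
    """Confidence-scored box from an external detector's label file."""

    bbox: tuple[float, float, float, float]
    confidence: float
    lesion_class: str = MA

    def __post_init__(self) -> None:
        x_min, y_min, x_max, y_max = self.bbox
        if not (x_min < x_max and y_min < y_max):
            raise ValidationError(f"degenerate bbox {self.bbox}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValidationError(f"confidence {self.confidence} outside [0, 1]")


def as_array(obj: FundusImage | IntensityMap | BinaryMap | np.ndarray) -> np.ndarray:
    """Unwrap any raster container to its ndarray."""
    if isinstance(obj, FundusImage):
        return obj.pixels
    if isinstance(obj, (IntensityMap, BinaryMap)):
        return obj.values
    return np.asarray(obj)
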