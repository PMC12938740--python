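"""Image operators that turn a colour fundus photo into a lesion candidate map.

The classical detection path prepares each image in five steps: a red/green
grayscale blend, large-kernel median filtering to estimate the slowly varying
background, an image difference that isolates small dark lesions, CLAHE to
restore local contrast, and adaptive thresholding to binarise lesion
candidates. Microaneurysms are *dark* blobs a few pixels across, so the
difference image encodes "darker than background" as values below the 128
mid-level and the threshold operates with ``polarity="dark"``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import exposure

from .types import BinaryMap, FundusImage, IntensityMap, ValidationError

#: shift added to the signed difference image so it fits the 8-bit domain
DIFF_OFFSET = 128


def to_grayscale(img: FundusImage) -> IntensityMap:
    """Equal red/green blend: ``Gray = 0.5 R + 0.5 G``, half-up rounding.

    The green channel carries the strongest contrast for red lesions; mixing
    in the red channel preserves background and vessel intensity cues in
    darker exposures. The blue channel is ignored. Exact integer arithmetic:
    ``(R + G + 1) // 2`` implements round-half-up of ``(R + G) / 2``.
    """
    if not isinstance(img, FundusImage):
        img = FundusImage(np.asarray(img))
    rg = img.pixels[:, :, 0].astype(np.uint16) + img.pixels[:, :, 1].astype(np.uint16)
    gray = ((rg + 1) // 2).astype(np.uint8)
    return IntensityMap(gray)


def median_filter(gray: IntensityMap, kernel_size: int = 25) -> IntensityMap:
    """Square median filter with reflection padding.

    With a kernel larger than the largest lesion (default 25 px, the upper
    bound of the microaneurysm size regime) the output is a background
    estimate: lesions vanish while illumination structure survives, so the
    subsequent difference image isolates the lesions.
    """
    kernel_size = int(kernel_size)
    if kernel_size < 3 or kernel_size % 2 == 0:
        raise ValidationError(f"kernel_size must be odd and >= 3, got {kernel_size}")
    out = ndimage.median_filter(gray.values, size=kernel_size, mode="reflect")
    return IntensityMap(out, domain=gray.domain)


def image_difference(gray: IntensityMap, background: IntensityMap) -> IntensityMap:
    """Signed difference ``gray - background``, shifted by +128 and clipped.

    A pixel equal to its background maps to 128; dark-on-background lesions
    map below 128. The shift keeps the result an 8-bit map while preserving
    the sign of the deviation.
    """
    if gray.values.shape != background.values.shape:
        raise ValidationError(
            f"dimension mismatch: {gray.values.shape} vs {background.values.shape}"
        )
    diff = gray.values.astype(np.int16) - background.values.astype(np.int16) + DIFF_OFFSET
    return IntensityMap(np.clip(diff, 0, 255).astype(np.uint8))


def clahe(
    gray: IntensityMap,
    clip_limit: float = 2.0,
    tiles: tuple[int, int] = (8, 8),
) -> IntensityMap:
    """Contrast-limited adaptive histogram equalisation.

    Per-tile clipped-histogram equalisation with bilinear interpolation
    between tile mappings. ``clip_limit`` follows the convention common in
    retinal imaging: the histogram is clipped at ``clip_limit`` times the
    height of a uniform histogram (values around 2 are typical; larger
    values allow more contrast amplification). ``tiles`` is the
    ``(nx, ny)`` grid of tiles, default 8x8.
    """
    if clip_limit <= 0:
        raise ValidationError(f"clip_limit must be positive, got {clip_limit}")
    nx, ny = int(tiles[0]), int(tiles[1])
    if nx < 1 or ny < 1:
        raise ValidationError(f"tile grid must be at least 1x1, got {tiles}")
    vals = gray.values
    if vals.min() == vals.max():
        # degenerate histogram: a constant image maps to a single level
        return IntensityMap(vals.astype(np.uint8).copy())
    nbins = 256
    # skimage expresses the clip as a fraction of the tile pixel count; a
    # uniform histogram bin holds 1/nbins of the tile, hence the conversion.
    frac = min(clip_limit / nbins, 1.0)
    kernel = (max(vals.shape[0] // ny, 1), max(vals.shape[1] // nx, 1))
    out = exposure.equalize_adapthist(
        vals.astype(np.uint8), kernel_size=kernel, clip_limit=frac, nbins=nbins
    )
    return IntensityMap(np.rint(out * 255).astype(np.uint8))


def _local_mean_times_n(values: np.ndarray, block_size: int) -> tuple[np.ndarray, int]:
    """Exact integer local sums over a block_size^2 window, reflect padding."""
    ones = np.ones(block_size, dtype=np.int64)
    sums = ndimage.correlate1d(values.astype(np.int64), ones, axis=0, mode="reflect")
    sums = ndimage.correlate1d(sums, ones, axis=1, mode="reflect")
    return sums, block_size * block_size


def adaptive_threshold(
    gray: IntensityMap,
    block_size: int = 31,
    offset: float = 6.0,
    polarity: str = "dark",
) -> BinaryMap:
    """Binarise against the local mean over a ``block_size`` square window.

    ``polarity="dark"`` marks pixels strictly below ``local_mean - offset``
    (microaneurysms are dark); ``"bright"`` marks pixels strictly above
    ``local_mean + offset``. Local sums are computed in exact integer
    arithmetic, so the output is invariant under a global additive shift of
    the input.
    """
    block_size = int(block_size)
    if block_size < 3 or block_size % 2 == 0:
        raise ValidationError(f"block_size must be odd and >= 3, got {block_size}")
    if polarity not in ("dark", "bright"):
        raise ValidationError(f"polarity must be 'dark' or 'bright', got {polarity!r}")
    sums, n = _local_mean_times_n(gray.values, block_size)
    vals = gray.values.astype(np.int64)
    # compare value < mean - offset without dividing: value*n < sum - offset*n
    if polarity == "dark":
        out = vals * n < sums - offset * n
    else:
        out = vals * n > sums + offset * n
    return BinaryMap(out)
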