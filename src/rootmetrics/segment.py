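"""Root/background segmentation of grayscale images.

Three thresholding families are provided, mirroring the routines common in
root-phenotyping software:

* a single global tonal threshold (optionally Otsu-selected): every pixel
  darker (or brighter, depending on polarity) than the threshold is root;
* a block-adaptive threshold: the image is tiled into
  square blocks, the mean intensity of each block is computed, and a pixel
  is root when it deviates from its block mean, in the polarity direction,
  by more than ``proportion`` of the tonal range;
* a double-adaptive threshold: the local mean is computed over a ladder of
  neighborhood sizes and a pixel is root when the mean moves monotonically
  away from the pixel value as the neighborhood grows, by at least
  ``min_change`` of the tonal range.  The monotonicity requirement
  suppresses paper-texture noise.

Polarity ``root_bright`` (the default) matches red-channel images of pale
roots on blue/grey germination paper; ``root_dark`` is the complement and
the two are exact duals under intensity inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .errors import DegenerateInputError, ParameterError
from .imaging import RasterImage

POLARITIES = ("root_bright", "root_dark")


@dataclass
class ThresholdParams:
    """Bundle of segmentation defaults for the batch pipeline."""

    polarity: str = "root_bright"
    global_t: float | None = None  # None = Otsu auto
    block_size: int = 64
    proportion: float = 0.1
    neighborhood_sizes: tuple[int, ...] = (5, 15, 31)
    min_change: float = 0.1

    def __post_init__(self) -> None:
        if self.polarity not in POLARITIES:
            raise ParameterError(f"polarity must be one of {POLARITIES}")
        if not (0 < self.proportion < 1):
            raise ParameterError("proportion must be in (0, 1)")
        if self.block_size < 3:
            raise ParameterError("block_size must be >= 3")
        if list(self.neighborhood_sizes) != sorted(set(self.neighborhood_sizes)):
            raise ParameterError("neighborhood_sizes must be strictly increasing")


@dataclass
class BinaryMask:
    """Boolean root mask aligned with its source image."""

    mask: np.ndarray
    mm_per_px: float = 0.13

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ParameterError("mask must be 2-D")

    @property
    def shape(self) -> tuple:
        return self.mask.shape

    def count(self) -> int:
        return int(self.mask.sum())


def _gray(image) -> tuple[np.ndarray, float, float]:
    """Return (2-D array, tonal max, mm_per_px) from RasterImage or ndarray."""
    if isinstance(image, RasterImage):
        if image.is_color:
            raise ParameterError("segmentation expects a grayscale image; use to_gray first")
        return image.pixels, image.max_value, image.mm_per_px
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ParameterError("expected a 2-D grayscale array")
    return arr, 255.0, 0.13


def global_threshold(image, t: float, polarity: str = "root_bright") -> BinaryMask:
    """Single global tonal threshold.

    root_dark: pixels strictly below ``t`` are root (everything at or above
    is background); root_bright is the mirror rule.
    """
    arr, maxv, mmpp = _gray(image)
    if not (0 <= t <= maxv):
        raise ParameterError(f"threshold {t} outside tonal range [0, {maxv}]")
    if polarity == "root_dark":
        mask = arr < t
    elif polarity == "root_bright":
        mask = arr > t
    else:
        raise ParameterError(f"polarity must be one of {POLARITIES}")
    return BinaryMask(mask, mmpp)


def auto_threshold(image) -> float:
    """Histogram-based (Otsu) global threshold selection.

    Returns a tonal value strictly between the image minimum and maximum;
    a constant image has no threshold and raises.
    """
    arr, maxv, _ = _gray(image)
    if arr.min() == arr.max():
        raise DegenerateInputError("constant image has no threshold")
    if np.all(arr == np.rint(arr)):
        # exact tonal histogram: the returned threshold is a tonal value
        counts = np.bincount(arr.astype(int).ravel(), minlength=int(maxv) + 1)
        centers = np.arange(counts.size, dtype=float)
        # Otsu labels the last tonal value of the lower class; +0.5 puts the
        # returned threshold strictly between the two classes
        return float(threshold_otsu(hist=(counts, centers))) + 0.5
    return float(threshold_otsu(arr, nbins=int(maxv) + 1))


def adaptive_threshold(
    image,
    block_size: int = 64,
    proportion: float = 0.1,
    polarity: str = "root_bright",
    smooth: bool = False,
) -> BinaryMask:
    """Block-mean adaptive threshold.

    The image is tiled into non-overlapping ``block_size`` squares (edge
    blocks smaller); a pixel is root when its polarity-signed deviation from
    the block mean exceeds ``proportion`` of the tonal range.  With
    ``smooth=True`` the tiled means are replaced by a per-pixel moving
    average of the same window, removing block seams.
    """
    arr, maxv, mmpp = _gray(image)
    h, w = arr.shape
    if block_size < 3:
        raise ParameterError("block_size must be >= 3")
    if block_size > h and block_size > w:
        raise ParameterError(f"block_size {block_size} exceeds both image dimensions {arr.shape}")
    if not (0 < proportion < 1):
        raise ParameterError("proportion must be in (0, 1)")

    if smooth:
        means = ndimage.uniform_filter(arr, size=block_size, mode="reflect")
    else:
        re = np.arange(0, h, block_size)
        ce = np.arange(0, w, block_size)
        sums = np.add.reduceat(np.add.reduceat(arr, re, axis=0), ce, axis=1)
        rl = np.diff(np.append(re, h))
        cl = np.diff(np.append(ce, w))
        block_means = sums / np.outer(rl, cl)
        means = np.repeat(np.repeat(block_means, rl, axis=0), cl, axis=1)

    dev = arr - means if polarity == "root_bright" else means - arr
    if polarity not in POLARITIES:
        raise ParameterError(f"polarity must be one of {POLARITIES}")
    return BinaryMask(dev > proportion * maxv, mmpp)


def double_adaptive_threshold(
    image,
    neighborhood_sizes: tuple[int, ...] = (5, 15, 31),
    min_change: float = 0.1,
    polarity: str = "root_bright",
) -> BinaryMask:
    """Neighborhood-ladder adaptive threshold.

    Local means m(s) are computed over square neighborhoods of each size in
    ``neighborhood_sizes``.  A pixel is root when (a) its polarity-signed
    deviation from m(s) exceeds ``min_change`` of the tonal range for some
    size and (b) the deviation grows monotonically with the neighborhood
    size, i.e. the local mean moves steadily away from the pixel value.
    Wide plateaus fail (b) in their interior and are rejected.
    """
    arr, maxv, mmpp = _gray(image)
    sizes = tuple(int(s) for s in neighborhood_sizes)
    if len(sizes) < 2:
        raise ParameterError("need at least two neighborhood sizes")
    if list(sizes) != sorted(set(sizes)):
        raise ParameterError("neighborhood_sizes must be strictly increasing")
    if polarity not in POLARITIES:
        raise ParameterError(f"polarity must be one of {POLARITIES}")

    sign = 1.0 if polarity == "root_bright" else -1.0
    devs = np.stack(
        [sign * (arr - ndimage.uniform_filter(arr, size=s, mode="reflect")) for s in sizes]
    )
    exceeded = devs.max(axis=0) > min_change * maxv
    monotone = np.all(np.diff(devs, axis=0) >= -1e-9, axis=0)
    return BinaryMask(exceeded & monotone, mmpp)


def clean_mask(mask: BinaryMask, min_object_px: int = 0, fill_holes: bool = False) -> BinaryMask:
    """Remove 8-connected specks smaller than ``min_object_px``; optionally
    fill fully enclosed holes."""
    if min_object_px < 0:
        raise ParameterError("min_object_px must be >= 0")
    out = mask.mask.copy()
    if min_object_px > 1:
        # max_size removes components of size <= value; we drop size < min_object_px
        out = remove_small_objects(out, max_size=min_object_px - 1, connectivity=2)
    if fill_holes:
        out = ndimage.binary_fill_holes(out)
    return BinaryMask(out, mask.mm_per_px)
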