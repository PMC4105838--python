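"""Raster image container and the two-flash preprocessing workflow.

Root systems grown on germination paper are photographed twice with
cross-polarized flash light, once illuminated from the left and once from
the right.  Specular glare (droplets, folds in the cover foil) appears at
different positions under the two illuminations, so a pixelwise *minimum
tonal* fusion of the pair suppresses it while retaining the cast shadows
that sharpen root/background contrast.  The full preprocessing chain is

    correct_illumination(left), correct_illumination(right)
        -> fuse_min -> to_gray (red channel by default)

Illumination correction is divisive flat-fielding: a smooth background
estimate (large-window median followed by Gaussian smoothing) divides the
image, and the result is rescaled to preserve the input mean.  Divisive
correction matches the multiplicative vignetting of flash lighting; thin
bright roots are rejected by the median window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .errors import ChannelError, DimensionError, InvariantError, ParameterError

_CHANNELS = {"red": 0, "green": 1, "blue": 2}


@dataclass
class RasterImage:
    """A 2-D (grayscale) or 3-D (RGB) intensity image with physical scale.

    Pixels are stored as float64 in native tonal units; ``bit_depth``
    declares the tonal range [0, 2**bit_depth - 1].  ``mm_per_px`` is the
    physical size of one pixel.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    mm_per_px: float = 0.13

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim not in (2, 3):
            raise DimensionError(f"expected 2-D or 3-D pixel array, got ndim={self.pixels.ndim}")
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise DimensionError(f"colour images must have 3 channels, got {self.pixels.shape[2]}")
        if min(self.pixels.shape[:2]) < 1:
            raise DimensionError("image must have at least one row and column")
        if self.mm_per_px <= 0:
            raise ParameterError("mm_per_px must be positive")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > self.max_value):
            raise InvariantError(
                f"intensities outside [0, {self.max_value}] for bit depth {self.bit_depth}"
            )

    @property
    def max_value(self) -> float:
        return float(2**self.bit_depth - 1)

    @property
    def is_color(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def to_uint8(self) -> np.ndarray:
        """Quantize to 8-bit for file output."""
        scale = 255.0 / self.max_value
        return np.clip(np.rint(self.pixels * scale), 0, 255).astype(np.uint8)


@dataclass
class FlatFieldModel:
    """Smooth, strictly positive background estimate used for division."""

    background: np.ndarray
    method: str = "median+gaussian"
    kernel_scale: int = 0

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)
        if self.background.size == 0 or self.background.min() <= 0:
            raise InvariantError("flat-field background must be strictly positive everywhere")


def imwrite(path: str | Path, image: RasterImage) -> None:
    """Write an image as 8-bit PNG/TIFF with a JSON sidecar recording the scale."""
    path = Path(path)
    iio.imwrite(path, image.to_uint8())
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(
        json.dumps({"mm_per_px": image.mm_per_px, "bit_depth": image.bit_depth}) + "\n"
    )


def imread(path: str | Path, mm_per_px: float | None = None) -> RasterImage:
    """Read a PNG/TIFF; the scale comes from the sidecar unless given explicitly."""
    path = Path(path)
    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    scale = mm_per_px if mm_per_px is not None else meta.get("mm_per_px", 0.13)
    return RasterImage(arr, bit_depth=int(meta.get("bit_depth", 8)), mm_per_px=scale)


def _check_pair(left: RasterImage, right: RasterImage) -> None:
    if left.shape != right.shape:
        raise DimensionError(f"image shapes differ: {left.shape} vs {right.shape}")
    if left.bit_depth != right.bit_depth:
        raise DimensionError("bit depths differ")


def fuse_min(left: RasterImage, right: RasterImage) -> RasterImage:
    """Pixelwise minimum of a left/right-illuminated pair (minimum tonal image).

    Bright specular artifacts present in only one of the two images are
    replaced by the darker (artifact-free) value from the other image.
    """
    _check_pair(left, right)
    return RasterImage(
        np.minimum(left.pixels, right.pixels),
        bit_depth=left.bit_depth,
        mm_per_px=left.mm_per_px,
    )


def _as_gray_array(image: RasterImage | np.ndarray) -> np.ndarray:
    arr = image.pixels if isinstance(image, RasterImage) else np.asarray(image, dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    return arr


def estimate_flatfield(image: RasterImage | np.ndarray, kernel_scale: int) -> FlatFieldModel:
    """Estimate the smooth illumination field of a root image.

    Medians over a coarse grid of ``kernel_scale``-sized windows (robust to
    thin bright roots) are interpolated back to full resolution and Gaussian
    smoothed.  ``kernel_scale`` should be at least ~5x the widest root so the
    median ignores root pixels.
    """
    arr = _as_gray_array(image)
    h, w = arr.shape
    if kernel_scale < 10:
        raise ParameterError("kernel_scale must be >= 10 px")
    if kernel_scale > max(h, w):
        raise ParameterError(f"kernel_scale {kernel_scale} exceeds image size {arr.shape}")

    half = kernel_scale // 2
    step = max(1, kernel_scale // 2)
    rows = np.arange(half, h, step)
    cols = np.arange(half, w, step)
    if rows[-1] != h - 1 - 0:  # always include a grid point near each border
        rows = np.unique(np.append(rows, h - 1))
    if cols[-1] != w - 1:
        cols = np.unique(np.append(cols, w - 1))
    rows = np.unique(np.insert(rows, 0, 0))
    cols = np.unique(np.insert(cols, 0, 0))

    # truncated border windows are anchored at their centroid, not the border,
    # so a linear trend extrapolates correctly to the image edge
    row_spans = [(max(0, r - half), min(h, r + half + 1)) for r in rows]
    col_spans = [(max(0, c - half), min(w, c + half + 1)) for c in cols]
    row_pos = np.array([(r0 + r1 - 1) / 2.0 for r0, r1 in row_spans])
    col_pos = np.array([(c0 + c1 - 1) / 2.0 for c0, c1 in col_spans])
    med = np.empty((rows.size, cols.size))
    for i, (r0, r1) in enumerate(row_spans):
        for j, (c0, c1) in enumerate(col_spans):
            med[i, j] = np.median(arr[r0:r1, c0:c1])

    interp = RegularGridInterpolator(
        (row_pos, col_pos), med, bounds_error=False, fill_value=None
    )
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    bg = interp(np.stack([rr.ravel(), cc.ravel()], axis=1)).reshape(h, w)
    # odd reflection continues linear gradients through the border, so the
    # final smoothing does not flatten the field at the image edge
    sigma = kernel_scale / 8.0
    pad = min(int(3 * sigma) + 1, min(h, w) - 1)
    padded = np.pad(bg, pad, mode="reflect", reflect_type="odd")
    bg = ndimage.gaussian_filter(padded, sigma=sigma, mode="nearest")[
        pad : pad + h, pad : pad + w
    ]
    bg = np.maximum(bg, 1e-3)
    return FlatFieldModel(bg, kernel_scale=kernel_scale)


def correct_illumination(image: RasterImage, model: FlatFieldModel) -> RasterImage:
    """Divide out the flat-field estimate, preserving the image mean.

    Works per channel for RGB input (one shared background field); output is
    clipped to the tonal range.
    """
    bg = model.background
    if bg.shape != image.pixels.shape[:2]:
        raise DimensionError(f"model shape {bg.shape} does not match image {image.shape}")
    if image.is_color:
        bg = bg[:, :, None]
    ratio = image.pixels / bg
    mean_ratio = ratio.mean()
    if mean_ratio <= 0:
        corrected = np.zeros_like(ratio)
    else:
        corrected = ratio * (image.pixels.mean() / mean_ratio)
    corrected = np.clip(corrected, 0.0, image.max_value)
    return RasterImage(corrected, bit_depth=image.bit_depth, mm_per_px=image.mm_per_px)


def to_gray(image: RasterImage, channel: str = "red") -> RasterImage:
    """Extract one colour channel (or the channel mean) as grayscale.

    On blue or grey germination papers the red channel carries the strongest
    root/background contrast and is the default downstream.
    """
    if not image.is_color:
        if channel == "mean":
            return RasterImage(image.pixels.copy(), image.bit_depth, image.mm_per_px)
        raise ChannelError(f"single-channel image has no '{channel}' channel")
    if channel == "mean":
        gray = image.pixels.mean(axis=2)
    elif channel in _CHANNELS:
        gray = image.pixels[:, :, _CHANNELS[channel]]
    else:
        raise ChannelError(f"unknown channel '{channel}' (expected red/green/blue/mean)")
    return RasterImage(gray.copy(), image.bit_depth, image.mm_per_px)


def preprocess(
    left: RasterImage,
    right: RasterImage,
    channel: str = "red",
    kernel_scale: int | None = None,
) -> RasterImage:
    """Full preprocessing: per-image illumination correction, minimum-tonal
    fusion of the left/right flash pair, then channel extraction."""
    _check_pair(left, right)
    h, w = left.shape[:2]
    if kernel_scale is None:
        kernel_scale = max(10, min(101, min(h, w) // 2))
    out = []
    for img in (left, right):
        model = estimate_flatfield(img, kernel_scale)
        out.append(correct_illumination(img, model))
    fused = fuse_min(out[0], out[1])
    if fused.is_color:
        return to_gray(fused, channel)
    return to_gray(fused, "mean") if channel == "mean" else fused
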