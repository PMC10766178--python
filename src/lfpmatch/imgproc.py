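"""Image enhancement chain: grayscale conversion, normalization, binarization.

A latent fingerprint photograph passes through three fixed stages before any
feature extraction: the color image is reduced to a single luminance channel,
the grayscale image is brought to a prescribed mean and variance so that
exposure and contrast differences between photographs cancel, and finally the
pixels are classified into ridge (1) and background (0) by thresholding.

Coordinate convention (shared by every module): origin at the top-left
corner, ``x`` is the column index, ``y`` the row index, both 0-based, and a
pixel occupies the unit square anchored at its indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from skimage.filters import threshold_otsu

from .errors import DegenerateImageError, InvalidImageError

__all__ = [
    "RgbImage",
    "GrayImage",
    "BinaryImage",
    "to_grayscale",
    "normalize",
    "binarize",
    "ensure_ridge_polarity",
]

#: Rec.601 luma weights used for the RGB -> grayscale reduction.
REC601_WEIGHTS = (0.299, 0.587, 0.114)

MIN_SIDE = 16


@dataclass(frozen=True)
class RgbImage:
    """An 8-bit H x W x 3 color raster."""

    pixels: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3 or p.size == 0:
            raise InvalidImageError(f"expected H x W x 3 array, got shape {p.shape}")
        if p.shape[0] < MIN_SIDE or p.shape[1] < MIN_SIDE:
            raise InvalidImageError(
                f"image {p.shape[0]}x{p.shape[1]} smaller than {MIN_SIDE}px minimum"
            )
        if p.min() < 0 or p.max() > 255:
            raise InvalidImageError("channel values must lie in [0, 255]")
        object.__setattr__(self, "pixels", p)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class GrayImage:
    """A single-channel raster at a known stage of the enhancement chain.

    ``stage`` is ``"raw"`` straight after grayscale conversion (values in
    [0, 255]) or ``"normalized"`` after mean/variance normalization (finite
    real values on the target scale).
    """

    pixels: np.ndarray
    stage: Literal["raw", "normalized"] = "raw"

    def __post_init__(self):
        p = np.asarray(self.pixels, dtype=np.float64)
        if p.ndim != 2 or p.size == 0:
            raise InvalidImageError(f"expected 2-D array, got shape {p.shape}")
        if not np.all(np.isfinite(p)):
            raise InvalidImageError("non-finite pixel values")
        if self.stage == "raw" and (p.min() < 0 or p.max() > 255):
            raise InvalidImageError("raw-stage values must lie in [0, 255]")
        object.__setattr__(self, "pixels", p)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class BinaryImage:
    """A {0, 1} raster; ``ridge_is_one`` asserts that 1 marks ridge pixels."""

    pixels: np.ndarray
    ridge_is_one: bool = True

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 2 or p.size == 0:
            raise InvalidImageError(f"expected 2-D array, got shape {p.shape}")
        if not np.isin(p, (0, 1)).all():
            raise InvalidImageError("binary image must contain only 0 and 1")
        object.__setattr__(self, "pixels", p.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def to_grayscale(img: RgbImage) -> GrayImage:
    """Reduce a color photograph to luminance with Rec.601 weights.

    Achromatic input (r = g = b) maps to the common channel value exactly;
    otherwise the weighted sum is rounded to the nearest integer so the raw
    grayscale stage stays on the 8-bit scale.
    """
    if not isinstance(img, RgbImage):
        img = RgbImage(np.asarray(img))
    w = np.array(REC601_WEIGHTS)
    gray = np.rint(img.pixels.astype(np.float64) @ w)
    return GrayImage(np.clip(gray, 0, 255), stage="raw")


def normalize(
    img: GrayImage, target_mean: float = 128.0, target_variance: float = 2000.0
) -> GrayImage:
    """Bring the image to a prescribed sample mean and variance.

    The classic per-pixel affine-per-side map: pixels above the current mean
    are stretched by ``sqrt(v0/var)`` above ``target_mean``, pixels below are
    stretched below it, so the output mean is exactly ``target_mean`` and the
    output variance ``target_variance`` (the two sides share the same gain,
    so this is a single affine map; the per-side form keeps the fixed-point
    property explicit).

    Raises
    ------
    DegenerateImageError
        If the image is constant (zero variance).
    """
    p = img.pixels
    mean = p.mean()
    var = p.var()
    if var == 0:
        raise DegenerateImageError("constant image cannot be normalized")
    gain = np.sqrt(target_variance / var)
    out = target_mean + gain * (p - mean)
    return GrayImage(out, stage="normalized")


def _otsu_threshold(p: np.ndarray) -> float:
    # 8-bit (integer-valued) images use an exact integer-histogram argmax of
    # the between-class variance so the threshold agrees with exhaustive
    # search over 0..255; real-valued (normalized) images fall back to
    # skimage's 256-bin Otsu.
    if p.min() >= 0 and p.max() <= 255 and np.allclose(p, np.round(p)):
        hist = np.bincount(p.astype(int).ravel(), minlength=256).astype(float)
        n = hist.sum()
        idx = np.arange(256)
        w0 = np.cumsum(hist)
        w1 = n - w0
        m0 = np.where(w0 > 0, np.cumsum(hist * idx) / np.maximum(w0, 1), 0.0)
        total = (hist * idx).sum()
        m1 = np.where(w1 > 0, (total - np.cumsum(hist * idx)) / np.maximum(w1, 1), 0.0)
        between = np.where((w0 > 0) & (w1 > 0), w0 * w1 * (m0 - m1) ** 2, -1.0)
        return float(np.argmax(between))
    return float(threshold_otsu(p, nbins=256))


def binarize(img: GrayImage, method: str = "otsu", threshold: float | None = None) -> BinaryImage:
    """Classify pixels into 1 (above threshold) and 0 (below).

    ``method="otsu"`` picks the threshold maximizing between-class variance;
    ``method="fixed"`` uses the supplied ``threshold``. The polarity of the
    result (whether 1 is ridge) depends on the imaging modality and is fixed
    afterwards by :func:`ensure_ridge_polarity`.
    """
    p = img.pixels
    if p.max() == p.min():
        raise DegenerateImageError("constant image cannot be binarized")
    if method == "otsu":
        t = _otsu_threshold(p)
    elif method == "fixed":
        if threshold is None:
            raise InvalidImageError("fixed binarization requires a threshold")
        t = float(threshold)
    else:
        raise InvalidImageError(f"unknown binarization method {method!r}")
    return BinaryImage((p > t).astype(np.uint8), ridge_is_one=True)


def binarize_adaptive(img: GrayImage, block_size: int = 16) -> BinaryImage:
    """Block-wise Otsu for unevenly illuminated photographs.

    Each ``block_size`` x ``block_size`` tile is thresholded with the Otsu
    value of a window three blocks wide centred on it; constant windows fall
    back to the global threshold.
    """
    p = img.pixels
    if p.max() == p.min():
        raise DegenerateImageError("constant image cannot be binarized")
    h, w = p.shape
    t_global = _otsu_threshold(p)
    out = np.zeros_like(p, dtype=np.uint8)
    for by in range(0, h, block_size):
        for bx in range(0, w, block_size):
            y0, y1 = max(0, by - block_size), min(h, by + 2 * block_size)
            x0, x1 = max(0, bx - block_size), min(w, bx + 2 * block_size)
            win = p[y0:y1, x0:x1]
            t = t_global if win.max() == win.min() else _otsu_threshold(win)
            tile = p[by : by + block_size, bx : bx + block_size]
            out[by : by + block_size, bx : bx + block_size] = (tile > t).astype(np.uint8)
    return BinaryImage(out, ridge_is_one=True)


def segment_foreground(
    img: GrayImage, block_size: int = 16, exclusion_px: float = 10.0
) -> np.ndarray:
    """Pixel map of where actual ridge structure is present.

    Latent-print photographs contain regions with no usable signal —
    occlusions, smudges, bare substrate texture. Ridge structure carries
    energy in a band around the ridge frequency, so every pixel is scored by
    the locally averaged energy of a band-passed copy of the image and
    compared against the well-imaged area (a fraction of its 75th
    percentile). Pixels within ``exclusion_px`` of a rejected region are
    rejected too, because features at the rim of a dropout are truncation
    artifacts. ``block_size`` sets the local-averaging scale.
    """
    from scipy import ndimage

    p = img.pixels
    band = ndimage.gaussian_filter(p, 1.0) - ndimage.gaussian_filter(p, 4.0)
    energy = ndimage.gaussian_filter(band**2, block_size * 0.375)
    thr = 0.18 * np.percentile(energy, 75)
    valid = energy >= thr
    dist = ndimage.distance_transform_edt(valid)
    return dist > exclusion_px


def ensure_ridge_polarity(
    binary: BinaryImage, gray: GrayImage, modality: str
) -> BinaryImage:
    """Flip the binary image, if needed, so that 1 always marks ridge pixels.

    An inked control has dark ridges on a light card, so the ridge class is
    the one with the lower mean grayscale value. A powder-developed latent
    print fluoresces under 365 nm UV, so its ridges are the brighter class.
    Applying the operation twice is a no-op.
    """
    if modality not in ("inked_control", "fluorescent_sample"):
        raise InvalidImageError(f"unknown modality {modality!r}")
    p = binary.pixels.astype(bool)
    if p.all() or (~p).all():
        # one-class image: nothing to decide
        return BinaryImage(binary.pixels, ridge_is_one=True)
    mean_one = gray.pixels[p].mean()
    mean_zero = gray.pixels[~p].mean()
    one_is_bright = mean_one > mean_zero
    want_bright = modality == "fluorescent_sample"
    if one_is_bright == want_bright:
        return BinaryImage(binary.pixels, ridge_is_one=True)
    return BinaryImage(1 - binary.pixels, ridge_is_one=True)
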