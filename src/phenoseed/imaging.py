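"""Low-level image transforms feeding the seed counter.

Grayscale conversion, Gaussian smoothing, automatic threshold selection
(Otsu's method) and binarization.  These are the preprocessing and
thresholding stages of the counting pipeline; they accept and return the
8-bit image types from :mod:`phenoseed.types`.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from phenoseed.types import BinaryMask, GrayImage, InvalidInputError, RasterImage

# ITU-R BT.601 luma weights — the de facto grayscale convention of
# imaging libraries, chosen for bit-reproducibility.
_BT601 = np.array([0.299, 0.587, 0.114])


class DegenerateHistogramError(InvalidInputError):
    """The image has a single intensity value; no threshold separates it."""


def to_grayscale(img: RasterImage) -> GrayImage:
    """Convert an RGB image to 8-bit luminance.

    Uses BT.601 weights (0.299 R + 0.587 G + 0.114 B) with half-up
    rounding, so a pure gray pixel (v, v, v) maps to exactly v.
    """
    luma = img.pixels.astype(np.float64) @ _BT601
    return GrayImage(np.floor(luma + 0.5).astype(np.uint8))


def gaussian_kernel(kernel_px: int, sigma: float) -> np.ndarray:
    """One-dimensional Gaussian kernel of odd length, normalized to sum 1."""
    if kernel_px < 1 or kernel_px % 2 == 0:
        raise InvalidInputError(f"kernel size must be odd and >= 1, got {kernel_px}")
    if not sigma > 0:
        raise InvalidInputError(f"sigma must be positive, got {sigma}")
    half = kernel_px // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def gaussian_blur(img: GrayImage, kernel_px: int = 5, sigma: float = 1.0) -> GrayImage:
    """Separable Gaussian smoothing with reflect border handling.

    The truncated kernel is renormalized to sum 1, so constant images
    pass through unchanged and output values stay within the input
    range (each output is a convex combination of inputs).  A kernel of
    size 1 is the identity.
    """
    k = gaussian_kernel(kernel_px, sigma)
    if kernel_px == 1:
        return GrayImage(img.pixels.copy())
    out = img.pixels.astype(np.float64)
    out = ndimage.convolve1d(out, k, axis=0, mode="reflect")
    out = ndimage.convolve1d(out, k, axis=1, mode="reflect")
    return GrayImage(np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8))


def otsu_threshold(img: GrayImage) -> int:
    """Threshold maximizing between-class variance of the 256-bin histogram.

    Returns the level ``t`` such that classes ``{pixel <= t}`` and
    ``{pixel > t}`` have maximal between-class variance; ties are broken
    by the smallest level.

    Raises
    ------
    DegenerateHistogramError
        If the image contains fewer than two distinct intensities.
    """
    hist = np.bincount(img.pixels.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError(
            "constant image: need at least two distinct intensity values"
        )
    p = hist / hist.sum()
    levels = np.arange(256, dtype=np.float64)
    omega = np.cumsum(p)                # class-0 probability at each candidate t
    mu = np.cumsum(p * levels)          # first moment up to t
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return int(np.argmax(sigma_b))      # argmax takes the first (smallest) maximizer


def binarize(img: GrayImage, level: int, polarity: str = "auto") -> BinaryMask:
    """Threshold a gray image into a {0, 1} foreground mask.

    Parameters
    ----------
    level
        Threshold intensity in [0, 255].
    polarity
        ``"bright"``: pixels strictly above ``level`` become foreground.
        ``"dark"``: pixels at or below ``level`` become foreground.
        ``"auto"``: pick whichever polarity yields a minority foreground
        (< 0.5 of pixels) — seeds occupy a small part of a counting
        image regardless of whether the background is white paper or a
        black table.
    """
    if not 0 <= level <= 255:
        raise InvalidInputError(f"threshold level {level} outside [0, 255]")
    if polarity not in ("bright", "dark", "auto"):
        raise InvalidInputError(f"unknown polarity {polarity!r}")
    bright = (img.pixels > level).astype(np.uint8)
    if polarity == "auto":
        polarity = "bright" if bright.mean() < 0.5 else "dark"
    if polarity == "bright":
        return BinaryMask(bright, foreground_polarity="bright")
    return BinaryMask(1 - bright, foreground_polarity="dark")
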