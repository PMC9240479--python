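"""Excess-green vegetation pre-segmentation.

The excess-green index 2g - r - b is high on chlorophyll-rich pixels and
near zero on achromatic soil; Otsu's histogram threshold then separates
plant from background, and the binary mask zeroes out non-vegetation
pixels of the original image.
"""

from __future__ import annotations

import numpy as np


class VegetationError(ValueError):
    pass


def excess_green(img: np.ndarray) -> np.ndarray:
    """Per-pixel 2*G - R - B on raw 0-255 channels, clamped to [0, 255].

    Returns a uint8 grayscale image. Saturated green (0,255,0) maps to
    255; achromatic pixels map to 0.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise VegetationError("excess_green expects an H x W x 3 image")
    r = img[..., 0].astype(np.int32)
    g = img[..., 1].astype(np.int32)
    b = img[..., 2].astype(np.int32)
    return np.clip(2 * g - r - b, 0, 255).astype(np.uint8)


def otsu_threshold(gray: np.ndarray) -> int:
    """Otsu's threshold over the 256-bin histogram.

    Returns the threshold t maximizing the between-class variance
    omega0 * omega1 * (mu0 - mu1)^2 where class 0 is {v <= t} and class 1
    is {v > t}; ties break toward the lowest maximizing t. A constant
    image has no separable classes and is rejected.
    """
    gray = np.asarray(gray)
    hist = np.bincount(gray.ravel().astype(np.intp), minlength=256)[:256].astype(np.float64)
    total = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise VegetationError("constant image: Otsu threshold undefined")
    w0 = np.cumsum(hist)                    # pixels with value <= t
    m0 = np.cumsum(hist * np.arange(256))   # intensity mass <= t
    w1 = total - w0
    mu0 = np.divide(m0, w0, out=np.zeros(256), where=w0 > 0)
    mu1 = np.divide(m0[-1] - m0, w1, out=np.zeros(256), where=w1 > 0)
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    return int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximizer


def binarize(gray: np.ndarray, threshold: int) -> np.ndarray:
    """Boolean mask: pixel true iff gray value is strictly above threshold."""
    if not 0 <= threshold <= 255:
        raise VegetationError("threshold must lie in [0, 255]")
    return np.asarray(gray) > threshold


def apply_mask(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Keep pixels where mask is true, paint the rest black."""
    img = np.asarray(img)
    mask = np.asarray(mask, dtype=bool)
    if img.shape[:2] != mask.shape:
        raise VegetationError(
            f"size mismatch: image {img.shape[:2]} vs mask {mask.shape}")
    out = np.zeros_like(img)
    out[mask] = img[mask]
    return out


def vegetation_mask(img: np.ndarray) -> np.ndarray:
    """Full pre-segmentation: excess_green -> Otsu -> binarize."""
    gray = excess_green(img)
    return binarize(gray, otsu_threshold(gray))
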