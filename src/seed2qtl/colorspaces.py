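"""Color-space conversions on a common 8-bit scale.

All 48 color descriptors are reported on an 8-bit scale so they are directly
comparable across spaces:

* ``RGB``   — sRGB channels as-is, 0..255.
* ``HSV``   — hue 0..360 deg mapped to 0..255; saturation and value 0..255.
* ``Lab``   — CIE L*a*b* (D65, sRGB): L* 0..100 mapped to 0..255; a*, b*
  offset by +128 and clipped.
* ``YCrCb`` — full-range ITU-R BT.601: Y = 0.299R + 0.587G + 0.114B;
  Cr, Cb offset by +128 (JPEG convention).

sRGB linearization helpers used by color calibration live here too.
"""

from __future__ import annotations

import numpy as np
from skimage import color as skcolor

COLOR_SPACES = ("RGB", "HSV", "Lab", "YCrCb")

# channel letters used in descriptor names, per space
CHANNELS = {
    "RGB": ("R", "G", "B"),
    "HSV": ("H", "S", "V"),
    "Lab": ("L", "a", "b"),
    "YCrCb": ("Y", "Cr", "Cb"),
}


def srgb_to_linear(rgb01: np.ndarray) -> np.ndarray:
    """sRGB electro-optical transfer: gamma-encoded [0,1] -> linear [0,1]."""
    rgb01 = np.asarray(rgb01, dtype=float)
    return np.where(rgb01 <= 0.04045, rgb01 / 12.92, ((rgb01 + 0.055) / 1.055) ** 2.4)


def linear_to_srgb(lin: np.ndarray) -> np.ndarray:
    lin = np.clip(np.asarray(lin, dtype=float), 0.0, 1.0)
    return np.where(lin <= 0.0031308, lin * 12.92, 1.055 * lin ** (1 / 2.4) - 0.055)


def rgb8_to_space(pixels: np.ndarray, space: str) -> np.ndarray:
    """Convert (N, 3) 8-bit sRGB pixels into ``space`` on the 8-bit scale."""
    px = np.asarray(pixels, dtype=float)
    if px.ndim != 2 or px.shape[1] != 3:
        raise ValueError("pixels must be an (N, 3) array")
    if space == "RGB":
        return px.copy()
    rgb01 = px[None, :, :] / 255.0  # skimage wants an image; fake a 1-row one
    if space == "HSV":
        hsv = skcolor.rgb2hsv(rgb01)[0]
        return hsv * 255.0
    if space == "Lab":
        lab = skcolor.rgb2lab(rgb01)[0]
        out = np.empty_like(lab)
        out[:, 0] = lab[:, 0] * 255.0 / 100.0
        out[:, 1] = lab[:, 1] + 128.0
        out[:, 2] = lab[:, 2] + 128.0
        return np.clip(out, 0.0, 255.0)
    if space == "YCrCb":
        r, g, b = px[:, 0], px[:, 1], px[:, 2]
        y = 0.299 * r + 0.587 * g + 0.114 * b
        cr = (r - y) * 0.713 + 128.0
        cb = (b - y) * 0.564 + 128.0
        return np.clip(np.stack([y, cr, cb], axis=1), 0.0, 255.0)
    raise ValueError(f"unknown color space: {space!r}")
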