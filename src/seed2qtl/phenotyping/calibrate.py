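"""Card detection, color correction and pixel-scale estimation.

The calibration card is localized as the dominant dark connected component on
the near-white background.  Its 24 patches are sampled at known layout
positions, and an affine color correction (3x3 matrix + offset, fitted and
applied in linearized sRGB) maps measured patch colors onto their nominal
values.  The mm-per-pixel scale follows from the card's known physical width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .. import colorchecker as cc
from ..colorspaces import linear_to_srgb, srgb_to_linear

__all__ = [
    "ColorCalibration",
    "CardNotFoundError",
    "AmbiguousCardError",
    "detect_card_and_calibrate",
    "apply_correction",
    "identity_calibration",
]


class CardNotFoundError(RuntimeError):
    pass


class AmbiguousCardError(RuntimeError):
    pass


@dataclass
class ColorCalibration:
    """Fitted calibration for one image."""

    card_bbox: tuple[int, int, int, int]      # (row0, col0, row1, col1), half-open
    patch_measured: np.ndarray                # (24, 3) measured patch colors, 8-bit
    matrix: np.ndarray                        # 3x3, linear-RGB domain
    offset: np.ndarray                        # (3,), linear-RGB domain
    scale_mm_per_px: float
    residual: float                           # mean per-patch abs error, 8-bit units

    def validate(self) -> None:
        if self.scale_mm_per_px <= 0:
            raise ValueError("scale must be positive")


def _otsu(values: np.ndarray) -> float:
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(values))


def _find_card_bbox(image: np.ndarray, min_frac: float = 0.05) -> tuple[int, int, int, int]:
    gray = image.astype(float).mean(axis=2)
    thr = _otsu(gray)
    dark = gray < thr
    lab, n = ndimage.label(dark)
    if n == 0:
        raise CardNotFoundError("no non-background components found")
    objs = ndimage.find_objects(lab)
    img_area = image.shape[0] * image.shape[1]
    cands = []
    for sl in objs:
        if sl is None:
            continue
        bbox_area = (sl[0].stop - sl[0].start) * (sl[1].stop - sl[1].start)
        if bbox_area >= min_frac * img_area:
            cands.append(sl)
    if not cands:
        raise CardNotFoundError("no component large enough to be the card")
    if len(cands) > 1:
        raise AmbiguousCardError(f"{len(cands)} card-sized components found")
    sl = cands[0]
    return (sl[0].start, sl[1].start, sl[0].stop, sl[1].stop)


def _sample_patches(image: np.ndarray, bbox: tuple[int, int, int, int]) -> np.ndarray:
    r0, c0, r1, c1 = bbox
    centers, (pw, ph) = cc.patch_centers_and_size(c1 - c0, r1 - r0)
    out = np.empty((cc.N_PATCHES, 3), dtype=float)
    for k, (px, py) in enumerate(centers):
        hw, hh = 0.3 * pw, 0.3 * ph  # central region only, away from gaps
        rr0, rr1 = int(r0 + py - hh), int(r0 + py + hh) + 1
        cc0, cc1 = int(c0 + px - hw), int(c0 + px + hw) + 1
        out[k] = np.median(image[rr0:rr1, cc0:cc1].reshape(-1, 3), axis=0)
    return out


def detect_card_and_calibrate(image: np.ndarray) -> ColorCalibration:
    """Locate the 24-patch card, fit the color correction and the pixel scale.

    Raises :class:`CardNotFoundError` / :class:`AmbiguousCardError` when zero
    or several card-sized dark components are present.
    """
    image = np.asarray(image)
    bbox = _find_card_bbox(image)
    measured = _sample_patches(image, bbox)
    meas_lin = srgb_to_linear(measured / 255.0)
    ref_lin = srgb_to_linear(cc.PATCH_SRGB.astype(float) / 255.0)
    design = np.hstack([meas_lin, np.ones((cc.N_PATCHES, 1))])
    coef, *_ = np.linalg.lstsq(design, ref_lin, rcond=None)
    matrix = coef[:3].T
    offset = coef[3]
    corrected = linear_to_srgb(meas_lin @ matrix.T + offset) * 255.0
    residual = float(np.mean(np.abs(corrected - cc.PATCH_SRGB.astype(float))))
    scale = cc.CARD_WIDTH_MM / float(bbox[3] - bbox[1])
    calib = ColorCalibration(
        card_bbox=bbox,
        patch_measured=measured,
        matrix=matrix,
        offset=offset,
        scale_mm_per_px=scale,
        residual=residual,
    )
    calib.validate()
    return calib


def apply_correction(image: np.ndarray, calib: ColorCalibration) -> np.ndarray:
    """Apply the fitted affine correction in linear RGB; returns uint8."""
    lin = srgb_to_linear(np.asarray(image, dtype=float) / 255.0)
    lin = lin @ calib.matrix.T + calib.offset
    return np.clip(np.round(linear_to_srgb(lin) * 255.0), 0, 255).astype(np.uint8)


def identity_calibration(scale_mm_per_px: float) -> ColorCalibration:
    """A no-op calibration for images of known scale without a card."""
    return ColorCalibration(
        card_bbox=(0, 0, 0, 0),
        patch_measured=cc.PATCH_SRGB.astype(float).copy(),
        matrix=np.eye(3),
        offset=np.zeros(3),
        scale_mm_per_px=scale_mm_per_px,
        residual=0.0,
    )
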