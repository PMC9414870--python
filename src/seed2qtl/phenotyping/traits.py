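"""The 55 per-seed descriptors: 3 size, 4 shape, 48 color.

Size (mm / mm^2): sL, sW from the minimum-area rotated bounding rectangle,
sA from the pixel mask.  Shape (dimensionless): circularity sCi = 4*pi*A/P^2,
roundness sRo = 4*A/(pi*sL^2) (normalized so a circle scores 1), rugosity
sRg = P/P_convex (alias sRu), solidity sSo = A/A_convex.

Color, per color space (RGB, HSV, Lab, YCrCb; 8-bit scale throughout):
three mean descriptors ``<S>_m<j>`` — the per-channel mean after excluding,
per channel independently, pixels deviating more than 3 sd from that
channel's mean — and nine dominant-color descriptors ``<S>_dC<j>_<i>``: seed
pixels are clustered into three groups in the space's 3-D coordinates, the
clusters ranked by pixel count, and each cluster centroid's three components
reported.  Clustering uses a deterministic Lloyd iteration seeded at the
10th/50th/90th-percentile pixels along the pixel cloud's first principal
axis; ties in the count ranking are broken by descending mean luminance.
A 1-px boundary erosion keeps background-contaminated edge pixels out of the
color statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from ..colorspaces import CHANNELS, COLOR_SPACES, rgb8_to_space
from .calibrate import ColorCalibration
from .segment import SeedContour

__all__ = [
    "TRAIT_NAMES",
    "SIZE_TRAITS",
    "SHAPE_TRAITS",
    "COLOR_TRAITS",
    "measure_size",
    "measure_shape",
    "measure_color",
    "phenotype_image",
    "phenotype_genotype",
    "EmptyMaskError",
]

SIZE_TRAITS = ["sL", "sW", "sA"]
SHAPE_TRAITS = ["sCi", "sRo", "sRg", "sSo"]
COLOR_TRAITS = [
    name
    for space in COLOR_SPACES
    for name in (
        [f"{space}_m{ch}" for ch in CHANNELS[space]]
        + [f"{space}_dC{ch}_{i}" for ch in CHANNELS[space] for i in (1, 2, 3)]
    )
]
TRAIT_NAMES = SIZE_TRAITS + SHAPE_TRAITS + COLOR_TRAITS
assert len(TRAIT_NAMES) == 55

SIZE_SHAPE_TRAITS = SIZE_TRAITS + SHAPE_TRAITS


class EmptyMaskError(ValueError):
    pass


def measure_size(contour: SeedContour, calibration: ColorCalibration) -> dict[str, float]:
    """Seed length, width (mm) and projected area (mm^2)."""
    s = calibration.scale_mm_per_px
    return {
        "sL": contour.rect_length * s,
        "sW": contour.rect_width * s,
        "sA": contour.pixel_count * s * s,
    }


def measure_shape(contour: SeedContour) -> dict[str, float]:
    """Circularity, roundness, rugosity and solidity of one contour."""
    a, p = contour.area, contour.perimeter
    if a <= 0 or p <= 0:
        raise ValueError("zero area or perimeter")
    return {
        "sCi": 4.0 * np.pi * a / p**2,
        "sRo": 4.0 * a / (np.pi * contour.rect_length**2),
        "sRg": p / contour.hull_perimeter,
        "sSo": a / contour.hull_area,
    }


def _trimmed_channel_means(px: np.ndarray, n_sd: float = 3.0) -> np.ndarray:
    """Per-channel mean after excluding >n_sd outliers, channel-independently."""
    mean = px.mean(axis=0)
    sd = px.std(axis=0)
    out = np.empty(3)
    for j in range(3):
        if sd[j] == 0:
            out[j] = mean[j]
        else:
            keep = np.abs(px[:, j] - mean[j]) <= n_sd * sd[j]
            out[j] = px[keep, j].mean() if keep.any() else mean[j]
    return out


def dominant_colors(px: np.ndarray, luminance: np.ndarray, k: int = 3, max_iter: int = 100):
    """Deterministic k-means in one color space's 3-D coordinates.

    Returns (centroids, counts) ordered by descending pixel count, ties broken
    by descending mean member luminance.  If fewer than k distinct colors (or
    clusters empty out), the lowest-rank non-empty centroid is duplicated into
    the empty slots with count 0.
    """
    uniq, inv, ucounts = np.unique(px, axis=0, return_inverse=True, return_counts=True)
    if len(uniq) <= k:
        lum = np.array([luminance[inv == i].mean() for i in range(len(uniq))])
        order = np.lexsort((-lum, -ucounts))
        cents = [uniq[i].astype(float) for i in order]
        counts = [int(ucounts[i]) for i in order]
        while len(cents) < k:
            cents.append(cents[-1].copy())
            counts.append(0)
        return np.array(cents), np.array(counts)

    centered = px - px.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[0]
    order = np.argsort(proj, kind="stable")
    init_idx = [order[int(q * (len(px) - 1))] for q in (0.1, 0.5, 0.9)]
    cents = px[init_idx].astype(float)
    assign = np.full(len(px), -1)
    for _ in range(max_iter):
        d2 = ((px[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
        new_assign = d2.argmin(axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            sel = assign == j
            if sel.any():
                cents[j] = px[sel].mean(axis=0)
    counts = np.array([(assign == j).sum() for j in range(k)])
    lum = np.array([luminance[assign == j].mean() if counts[j] else -np.inf for j in range(k)])
    rank = np.lexsort((-lum, -counts))
    cents, counts = cents[rank], counts[rank]
    nonempty = counts > 0
    if not nonempty.all():
        last = np.where(nonempty)[0][-1]
        for j in np.where(~nonempty)[0]:
            cents[j] = cents[last]
    return cents, counts


def measure_color(
    image: np.ndarray,
    contour: SeedContour,
    calibration: ColorCalibration | None = None,
    n_sd: float = 3.0,
    erode_px: int = 1,
) -> dict[str, float]:
    """The 48 color descriptors of one seed from a color-corrected image."""
    mask = contour.mask
    if erode_px > 0:
        eroded = ndimage.binary_erosion(mask, iterations=erode_px)
        if eroded.any():
            mask = eroded
    if not mask.any():
        raise EmptyMaskError("no interior pixels to sample")
    r0, c0, r1, c1 = contour.bbox
    rgb = np.asarray(image[r0:r1, c0:c1], dtype=float)[mask]
    luminance = 0.299 * rgb[:, 0] + 0.587 * rgb[:, 1] + 0.114 * rgb[:, 2]
    out: dict[str, float] = {}
    for space in COLOR_SPACES:
        px = rgb8_to_space(rgb, space)
        means = _trimmed_channel_means(px, n_sd=n_sd)
        for j, ch in enumerate(CHANNELS[space]):
            out[f"{space}_m{ch}"] = float(means[j])
        cents, _ = dominant_colors(px, luminance)
        for j, ch in enumerate(CHANNELS[space]):
            for i in range(3):
                out[f"{space}_dC{ch}_{i + 1}"] = float(cents[i, j])
    return out


def phenotype_seed(image, contour, calibration, **color_kwargs) -> dict[str, float]:
    rec = measure_size(contour, calibration)
    rec.update(measure_shape(contour))
    rec.update(measure_color(image, contour, calibration, **color_kwargs))
    return rec


def phenotype_image(image, contours, calibration, image_id=None, **color_kwargs) -> pd.DataFrame:
    """Per-seed trait table (one row per contour, 55 trait columns)."""
    rows = []
    for i, ct in enumerate(contours, start=1):
        rec = {"image": image_id, "seed": i}
        rec.update(phenotype_seed(image, ct, calibration, **color_kwargs))
        rows.append(rec)
    return pd.DataFrame(rows, columns=["image", "seed"] + TRAIT_NAMES)


def phenotype_genotype(per_image_tables: list[pd.DataFrame]) -> tuple[pd.Series, pd.DataFrame]:
    """Pool per-seed tables across a genotype's images; unweighted trait means.

    Returns (genotype trait vector, pooled per-seed table).  Raises if no
    seed was detected in any image.
    """
    tables = [t for t in per_image_tables if len(t)]
    if not tables:
        raise EmptyMaskError("no seeds detected in any image of this genotype")
    pooled = pd.concat(tables, ignore_index=True)
    return pooled[TRAIT_NAMES].mean(axis=0), pooled
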