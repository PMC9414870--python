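"""Seed segmentation on a white background.

Objects darker than the background are thresholded on lightness (Otsu),
cleaned with a 3x3 morphological opening, labeled, and filtered by a minimum
physical area.  The card's bounding box is excluded.  Touching seeds are not
split: the imaging protocol scatters seeds so they do not touch.

Contours are traced at the 0.5 level of each object mask and lightly smoothed
with a short circular moving average before measurement; raw marching-squares
polygons overestimate the perimeter of smooth outlines by several percent,
which would bias circularity and rugosity.  Area and perimeter are then taken
on the same smoothed polygon, and convex-hull quantities on its vertex hull,
so solidity <= 1 and rugosity >= 1 hold by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage import measure
from skimage.filters import threshold_otsu

from .calibrate import ColorCalibration

__all__ = ["SeedContour", "segment_seeds", "smooth_polygon", "min_area_rect"]

DEFAULT_MIN_AREA_MM2 = 2.0
DEFAULT_SMOOTH_WINDOW = 5


@dataclass
class SeedContour:
    """One segmented seed: mask plus polygonal contour measurements (pixels)."""

    polygon: np.ndarray          # (N, 2) smoothed contour, (row, col), open ring
    mask: np.ndarray             # boolean, cropped to bbox
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1) of the crop
    pixel_count: int
    area: float                  # polygon (shoelace) area, px^2
    perimeter: float             # polygon perimeter, px
    hull_area: float
    hull_perimeter: float
    rect_length: float           # min-area rotated rectangle sides, px
    rect_width: float

    def validate(self) -> None:
        if self.area <= 0 or self.perimeter <= 0:
            raise ValueError("degenerate contour")
        if self.area > self.hull_area * (1 + 1e-9):
            raise ValueError("area exceeds convex-hull area")


def smooth_polygon(poly: np.ndarray, window: int) -> np.ndarray:
    """Circular moving average over the closed polygon's vertices."""
    if window <= 1 or len(poly) <= window:
        return poly
    acc = np.zeros_like(poly)
    for off in range(-(window // 2), window // 2 + 1):
        acc += np.roll(poly, off, axis=0)
    return acc / window


def _ring_perimeter(pts: np.ndarray) -> float:
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    return float(np.sqrt((d**2).sum(axis=1)).sum())


def _ring_area(pts: np.ndarray) -> float:
    x, y = pts[:, 1], pts[:, 0]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def min_area_rect(points: np.ndarray) -> tuple[float, float]:
    """(long side, short side) of the minimum-area rotated bounding rectangle.

    Rotating-calipers over the convex hull: the optimal rectangle is aligned
    with one hull edge.
    """
    hull = ConvexHull(points)
    v = points[hull.vertices]
    edges = np.diff(np.vstack([v, v[:1]]), axis=0)
    norms = np.linalg.norm(edges, axis=1)
    dirs = edges[norms > 0] / norms[norms > 0, None]
    best = None
    for d in dirs:
        n = np.array([-d[1], d[0]])
        p = v @ d
        q = v @ n
        w, h = p.max() - p.min(), q.max() - q.min()
        if best is None or w * h < best[0]:
            best = (w * h, max(w, h), min(w, h))
    return best[1], best[2]


def contour_from_mask(mask: np.ndarray, bbox=(0, 0), smooth_window: int = DEFAULT_SMOOTH_WINDOW) -> SeedContour:
    """Build a :class:`SeedContour` from a boolean object mask."""
    padded = np.pad(mask, 1).astype(float)
    conts = measure.find_contours(padded, 0.5)
    if not conts:
        raise ValueError("empty mask")
    poly = max(conts, key=len)[:-1] - 1.0  # drop repeated endpoint, undo pad
    if len(poly) < 3:
        raise ValueError("degenerate contour (<3 points)")
    poly = smooth_polygon(poly, smooth_window)
    poly_global = poly + np.array(bbox, dtype=float)
    hull = ConvexHull(poly)
    hv = poly[hull.vertices]
    sc = SeedContour(
        polygon=poly_global,
        mask=mask.copy(),
        bbox=(bbox[0], bbox[1], bbox[0] + mask.shape[0], bbox[1] + mask.shape[1]),
        pixel_count=int(mask.sum()),
        area=_ring_area(poly),
        perimeter=_ring_perimeter(poly),
        hull_area=float(hull.volume),
        hull_perimeter=_ring_perimeter(hv),
        rect_length=0.0,
        rect_width=0.0,
    )
    sc.rect_length, sc.rect_width = min_area_rect(poly)
    sc.validate()
    return sc


def segment_seeds(
    image: np.ndarray,
    calibration: ColorCalibration,
    min_area_mm2: float = DEFAULT_MIN_AREA_MM2,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    card_margin_px: int = 3,
) -> list[SeedContour]:
    """Segment seeds in a (color-corrected) image; the card region is excluded.

    Returns contours sorted by (row, col) of their bounding box; an empty list
    is a valid result.
    """
    gray = np.asarray(image, dtype=float).mean(axis=2)
    r0, c0, r1, c1 = calibration.card_bbox
    work = gray.copy()
    if r1 > r0 and c1 > c0:
        work[max(r0 - card_margin_px, 0): r1 + card_margin_px,
             max(c0 - card_margin_px, 0): c1 + card_margin_px] = gray.max()
    thr = threshold_otsu(work)
    objects = work < thr
    objects = ndimage.binary_opening(objects, structure=np.ones((3, 3)))
    lab, n = ndimage.label(objects)
    min_px = min_area_mm2 / calibration.scale_mm_per_px**2
    out = []
    for comp_id, sl in enumerate(ndimage.find_objects(lab), start=1):
        if sl is None:
            continue
        sub = lab[sl] == comp_id
        if sub.sum() < min_px:
            continue
        out.append(contour_from_mask(sub, bbox=(sl[0].start, sl[1].start), smooth_window=smooth_window))
    out.sort(key=lambda s: (s.bbox[0], s.bbox[1]))
    return out
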