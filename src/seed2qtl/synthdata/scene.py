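"""Synthetic seed-image renderer with exact ground truth.

Emulates the imaging protocol the phenotyping stage expects: seeds scattered
on a near-white background next to a 24-patch color calibration card, imaged
at a known mm-per-pixel scale.  Seed outlines are ellipses with an optional
low-order radial cosine perturbation, so length, width and area have closed
forms and can serve as oracles for the measurement code:

    r(theta) = (1 + rho * cos(m * theta)) on the unit ellipse,
    area = pi * a * b * (1 + rho^2 / 2)   (exactly pi*a*b for rho = 0).

An optional global linear color cast (3x3 matrix + offset in linearized RGB)
and per-channel Gaussian pixel noise exercise the calibration stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .. import colorchecker as cc
from ..colorspaces import linear_to_srgb, srgb_to_linear

__all__ = ["SeedGeom", "SceneSpec", "render_seed_image", "random_scene", "SceneError"]


class SceneError(ValueError):
    """Raised for invalid or unplaceable scene specifications."""


@dataclass
class SeedGeom:
    """Geometry and base coat color of one seed.

    Semi-axes ``a >= b`` are in mm; ``roughness`` is the radial perturbation
    amplitude rho in [0, 0.2]; ``lobes`` the cosine order m.
    """

    center_mm: tuple[float, float]
    a_mm: float
    b_mm: float
    angle_deg: float = 0.0
    roughness: float = 0.0
    lobes: int = 8
    color: tuple[int, int, int] = (139, 101, 57)

    @property
    def bounding_radius_mm(self) -> float:
        return self.a_mm * (1.0 + self.roughness)

    @property
    def true_area_mm2(self) -> float:
        return np.pi * self.a_mm * self.b_mm * (1.0 + self.roughness**2 / 2.0)

    def validate(self) -> None:
        if not (self.a_mm >= self.b_mm > 0):
            raise SceneError(f"require a >= b > 0, got a={self.a_mm}, b={self.b_mm}")
        if not (0.0 <= self.roughness <= 0.2):
            raise SceneError(f"roughness must be in [0, 0.2], got {self.roughness}")


@dataclass
class SceneSpec:
    """Full description of one synthetic image."""

    seeds: list[SeedGeom] = field(default_factory=list)
    scale_mm_per_px: float = 0.15
    width_mm: float = 170.0
    height_mm: float = 130.0
    card_origin_mm: tuple[float, float] = (4.0, 4.0)
    background_rgb: tuple[int, int, int] = (247, 247, 245)
    noise_sd: float = 0.0
    cast_matrix: np.ndarray | None = None   # 3x3, applied in linear RGB
    cast_offset: np.ndarray | None = None   # length 3, linear RGB units
    gamma: float = 1.0                      # encoded-domain gamma perturbation
    seed: int = 0

    @property
    def card_rect_mm(self) -> tuple[float, float, float, float]:
        x0, y0 = self.card_origin_mm
        return (x0, y0, x0 + cc.CARD_WIDTH_MM, y0 + cc.CARD_HEIGHT_MM)

    def validate(self) -> None:
        if self.scale_mm_per_px <= 0:
            raise SceneError("scale must be positive")
        if self.noise_sd < 0:
            raise SceneError("noise sd must be non-negative")
        x0, y0, x1, y1 = self.card_rect_mm
        if x0 < 0 or y0 < 0 or x1 > self.width_mm or y1 > self.height_mm:
            raise SceneError("card does not fit inside the image")
        for s in self.seeds:
            s.validate()
            cx, cy = s.center_mm
            r = s.bounding_radius_mm
            if cx - r < 0 or cy - r < 0 or cx + r > self.width_mm or cy + r > self.height_mm:
                raise SceneError(f"seed at ({cx}, {cy}) extends beyond the image")
            # disjoint from the card rectangle (bounding-circle test)
            nx = min(max(cx, x0), x1)
            ny = min(max(cy, y0), y1)
            if (cx - nx) ** 2 + (cy - ny) ** 2 <= r**2:
                raise SceneError(f"seed at ({cx}, {cy}) overlaps the card")
        for i in range(len(self.seeds)):
            for j in range(i + 1, len(self.seeds)):
                ci, cj = self.seeds[i], self.seeds[j]
                d2 = (ci.center_mm[0] - cj.center_mm[0]) ** 2 + (ci.center_mm[1] - cj.center_mm[1]) ** 2
                if d2 <= (ci.bounding_radius_mm + cj.bounding_radius_mm) ** 2:
                    raise SceneError(f"seeds {i} and {j} overlap")


def _draw_card(img: np.ndarray, spec: SceneSpec) -> None:
    s = spec.scale_mm_per_px
    x0, y0, x1, y1 = (v / s for v in spec.card_rect_mm)
    c0, r0, c1, r1 = int(round(x0)), int(round(y0)), int(round(x1)), int(round(y1))
    img[r0:r1, c0:c1] = cc.FRAME_RGB
    centers, (pw, ph) = cc.patch_centers_and_size(c1 - c0, r1 - r0)
    for k in range(cc.N_PATCHES):
        px, py = centers[k]
        cc0 = int(round(c0 + px - pw / 2))
        cc1 = int(round(c0 + px + pw / 2))
        rr0 = int(round(r0 + py - ph / 2))
        rr1 = int(round(r0 + py + ph / 2))
        img[rr0:rr1, cc0:cc1] = cc.PATCH_SRGB[k]


def _seed_mask(seed: SeedGeom, spec: SceneSpec, shape: tuple[int, int]):
    """Boolean mask of one seed plus its row/col slice in image coordinates."""
    s = spec.scale_mm_per_px
    cx, cy = seed.center_mm
    r = seed.bounding_radius_mm
    r0 = max(int((cy - r) / s) - 1, 0)
    r1 = min(int((cy + r) / s) + 2, shape[0])
    c0 = max(int((cx - r) / s) - 1, 0)
    c1 = min(int((cx + r) / s) + 2, shape[1])
    rows = (np.arange(r0, r1) + 0.5) * s
    cols = (np.arange(c0, c1) + 0.5) * s
    dx = cols[None, :] - cx
    dy = rows[:, None] - cy
    phi = np.deg2rad(seed.angle_deg)
    u = (dx * np.cos(phi) + dy * np.sin(phi)) / seed.a_mm
    v = (-dx * np.sin(phi) + dy * np.cos(phi)) / seed.b_mm
    rad2 = u**2 + v**2
    if seed.roughness > 0:
        theta = np.arctan2(v, u)
        lim = 1.0 + seed.roughness * np.cos(seed.lobes * theta)
        mask = rad2 <= lim**2
    else:
        mask = rad2 <= 1.0
    return mask, (slice(r0, r1), slice(c0, c1))


def render_seed_image(spec: SceneSpec):
    """Render a scene.

    Returns ``(image, labels, truth)``: an (H, W, 3) uint8 image, an (H, W)
    int32 label map (0 = background/card, k = seed k), and a ground-truth
    DataFrame with one row per seed (true length/width/area in mm and the
    base coat color before any cast or noise).
    """
    spec.validate()
    s = spec.scale_mm_per_px
    shape = (int(round(spec.height_mm / s)), int(round(spec.width_mm / s)))
    img = np.empty((*shape, 3), dtype=float)
    img[:] = spec.background_rgb
    labels = np.zeros(shape, dtype=np.int32)
    _draw_card(img, spec)

    rows = []
    for k, seed in enumerate(spec.seeds, start=1):
        mask, sl = _seed_mask(seed, spec, shape)
        img[sl][mask] = seed.color
        labels[sl][mask] = k
        rows.append(
            {
                "seed_id": k,
                "center_x_mm": seed.center_mm[0],
                "center_y_mm": seed.center_mm[1],
                "a_mm": seed.a_mm,
                "b_mm": seed.b_mm,
                "angle_deg": seed.angle_deg,
                "roughness": seed.roughness,
                "true_sL": 2.0 * seed.a_mm * (1.0 + seed.roughness),
                "true_sW": 2.0 * seed.b_mm,
                "true_sA": seed.true_area_mm2,
                "base_R": seed.color[0],
                "base_G": seed.color[1],
                "base_B": seed.color[2],
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "seed_id", "center_x_mm", "center_y_mm", "a_mm", "b_mm", "angle_deg",
            "roughness", "true_sL", "true_sW", "true_sA", "base_R", "base_G", "base_B",
        ],
    )

    if spec.cast_matrix is not None or spec.cast_offset is not None:
        m = np.eye(3) if spec.cast_matrix is None else np.asarray(spec.cast_matrix, dtype=float)
        o = np.zeros(3) if spec.cast_offset is None else np.asarray(spec.cast_offset, dtype=float)
        lin = srgb_to_linear(img / 255.0)
        lin = lin @ m.T + o
        img = linear_to_srgb(lin) * 255.0
    if spec.gamma != 1.0:
        img = ((img / 255.0) ** (1.0 / spec.gamma)) * 255.0
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8), labels, truth


def random_scene(
    n_seeds: int,
    seed: int = 0,
    a_range: tuple[float, float] = (3.0, 3.8),
    b_range: tuple[float, float] = (1.5, 2.0),
    roughness: float = 0.0,
    color: tuple[int, int, int] | None = None,
    color_jitter: float = 0.0,
    max_tries: int = 2000,
    **spec_kwargs,
) -> SceneSpec:
    """Place ``n_seeds`` non-overlapping seeds at random below/right of the card.

    Raises :class:`SceneError` if placement fails after ``max_tries`` draws,
    mirroring a physically overcrowded scene.
    """
    rng = np.random.default_rng(seed)
    spec = SceneSpec(seeds=[], seed=seed, **spec_kwargs)
    x0, y0, x1, y1 = spec.card_rect_mm
    placed: list[SeedGeom] = []
    tries = 0
    base_color = np.array(color if color is not None else (139, 101, 57), dtype=float)
    while len(placed) < n_seeds:
        if tries >= max_tries:
            raise SceneError(f"could not place {n_seeds} seeds after {max_tries} tries")
        tries += 1
        a = rng.uniform(*a_range)
        b = rng.uniform(min(b_range[0], a), min(b_range[1], a))
        r = a * (1.0 + roughness)
        cx = rng.uniform(r + 1.0, spec.width_mm - r - 1.0)
        cy = rng.uniform(r + 1.0, spec.height_mm - r - 1.0)
        nx = min(max(cx, x0 - 2), x1 + 2)
        ny = min(max(cy, y0 - 2), y1 + 2)
        if (cx - nx) ** 2 + (cy - ny) ** 2 <= (r + 1.0) ** 2:
            continue
        if any(
            (cx - p.center_mm[0]) ** 2 + (cy - p.center_mm[1]) ** 2
            <= (r + p.bounding_radius_mm + 1.0) ** 2
            for p in placed
        ):
            continue
        col = np.clip(base_color + rng.normal(0, color_jitter, 3), 0, 255).astype(int)
        placed.append(
            SeedGeom(
                center_mm=(float(cx), float(cy)),
                a_mm=float(a),
                b_mm=float(b),
                angle_deg=float(rng.uniform(0, 180)),
                roughness=roughness,
                color=tuple(int(c) for c in col),
            )
        )
    spec.seeds = placed
    spec.validate()
    return spec
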