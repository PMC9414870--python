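"""ICIM-style additive and digenic-epistasis QTL scans for RIL populations.

The scan follows the inclusive-composite-interval-mapping recipe with a
regression (Haley--Knott-style) likelihood:

1. Stepwise forward--backward selection of marker cofactors on the trait
   (entry/exit p-value thresholds, defaults 0.001 / 0.002).
2. At each scan position the phenotype is adjusted by the fitted effects of
   all selected cofactors *except* the markers flanking the current interval,
   then regressed on the expected QTL genotype E[x | flanking genotypes]
   computed from selfed-RIL conditional probabilities under the Haldane map
   function.  LOD = (n/2) * log10(RSS0 / RSS1).
3. Peaks are local LOD maxima above the detection threshold (2.0); peaks
   within a merge radius (10 cM) collapse to the higher one.  LOD in (2, 3]
   is classed "significant", above 3 "highly significant".  Support interval
   by the LOD-1 drop.

The epistasis scan walks a coarser grid (5 cM), fits both loci plus their
product, and reports pairs with interaction LOD >= 5 explaining >= 5% of the
phenotypic variance.  Same-chromosome pairs closer than 20 cM are excluded
to avoid linkage artifacts.  At marker positions with no cofactors the
additive LOD reduces algebraically to the single-marker regression LOD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ..synthdata.rilsim import ril_recombination
from .dataset import RilDataset
from .naming import name_qtl

__all__ = [
    "QtlResult",
    "EpistaticPair",
    "classify_significance",
    "select_cofactors",
    "additive_scan",
    "lod_at",
    "epistasis_scan",
    "scan_all_traits",
    "results_to_frame",
    "epistasis_to_frame",
]

LOD_SIGNIFICANT = 2.0
LOD_HIGHLY_SIGNIFICANT = 3.0


@dataclass
class QtlResult:
    trait: str
    chrom: str
    peak_cm: float
    lod: float
    pve: float
    effect: float
    ci_lo_cm: float
    ci_hi_cm: float
    left_marker: str
    right_marker: str
    significance: str
    name: str = ""

    def validate(self) -> None:
        if self.lod < 0 or not (0.0 <= self.pve <= 100.0):
            raise ValueError("invalid LOD or PVE")
        if not (self.ci_lo_cm <= self.peak_cm <= self.ci_hi_cm):
            raise ValueError("support interval must contain the peak")


@dataclass
class EpistaticPair:
    trait: str
    chrom_a: str
    pos_a_cm: float
    chrom_b: str
    pos_b_cm: float
    lod: float
    pve: float
    effect: float


def classify_significance(lod: float) -> str | None:
    """Fixed-threshold class: (2, 3] significant, > 3 highly significant."""
    if lod < 0:
        raise ValueError("negative LOD")
    if lod > LOD_HIGHLY_SIGNIFICANT:
        return "highly_significant"
    if lod > LOD_SIGNIFICANT:
        return "significant"
    return None


def _imputed_genotypes(ds: RilDataset) -> pd.DataFrame:
    x = ds.genotypes.astype(float)
    return x.fillna(x.mean()).fillna(0.0)


def select_cofactors(
    ds: RilDataset,
    trait: str,
    p_entry: float = 0.001,
    p_exit: float = 0.002,
    max_cofactors: int | None = None,
) -> dict[str, float]:
    """Stepwise forward-backward marker selection; returns {marker: coefficient}.

    Missing genotypes are mean-imputed for selection and adjustment.
    Collinear candidates (no residual variance) are skipped.
    """
    y = ds.phenotypes[trait].to_numpy(dtype=float)
    keep = np.isfinite(y)
    if keep.sum() < 10:
        raise ValueError("need >= 10 non-missing lines")
    y = y[keep]
    X = _imputed_genotypes(ds).to_numpy()[keep]
    markers = list(ds.genotypes.columns)
    n = len(y)
    if max_cofactors is None:
        max_cofactors = max(n // 10, 1)
    if np.std(y) == 0:
        return {}

    selected: list[int] = []
    while True:
        # backward: drop the worst cofactor while any exceeds the exit p
        while selected:
            D = np.column_stack([np.ones(n), X[:, selected]])
            coef, *_ = np.linalg.lstsq(D, y, rcond=None)
            resid = y - D @ coef
            df = n - D.shape[1]
            if df <= 0:
                selected.pop()
                continue
            sigma2 = resid @ resid / df
            cov = sigma2 * np.linalg.pinv(D.T @ D)
            tvals = coef[1:] / np.sqrt(np.maximum(np.diag(cov)[1:], 1e-300))
            pvals = 2 * stats.t.sf(np.abs(tvals), df)
            worst = int(np.argmax(pvals))
            if pvals[worst] > p_exit:
                selected.pop(worst)
            else:
                break
        if len(selected) >= max_cofactors:
            break
        # forward: residualize y and candidates on the current model
        D = np.column_stack([np.ones(n)] + ([X[:, selected]] if selected else []))
        Q, _ = np.linalg.qr(D)
        ry = y - Q @ (Q.T @ y)
        RX = X - Q @ (Q.T @ X)
        sy = np.sqrt(ry @ ry)
        sx = np.sqrt((RX**2).sum(axis=0))
        df = n - D.shape[1] - 1
        if sy <= 1e-12 or df <= 0:
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (RX.T @ ry) / (sx * sy)
        r[~np.isfinite(r)] = 0.0
        r[sx < 1e-8] = 0.0  # collinear with current model
        r[selected] = 0.0
        r = np.clip(r, -0.999999, 0.999999)
        tvals = r * np.sqrt(df / (1 - r**2))
        pvals = 2 * stats.t.sf(np.abs(tvals), df)
        best = int(np.argmin(pvals))
        if pvals[best] < p_entry:
            selected.append(best)
        else:
            break

    if not selected:
        return {}
    D = np.column_stack([np.ones(n), X[:, selected]])
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    return {markers[j]: float(coef[i + 1]) for i, j in enumerate(selected)}


def _expected_x(pos_cm: float, marker_pos: np.ndarray, geno: np.ndarray):
    """E[x | flanking genotypes] for all lines at one scan position.

    ``geno`` is (n_lines, n_markers) for one chromosome, +/-1 with NaN.
    Returns an (n_lines,) array with NaN where no flanking information exists.
    """
    i_r = int(np.searchsorted(marker_pos, pos_cm))
    i_l = i_r - 1
    if i_r < len(marker_pos) and marker_pos[i_r] == pos_cm:
        i_l = i_r
    n = geno.shape[0]
    t_plus = np.full(n, 1.0)
    t_minus = np.full(n, 1.0)
    any_info = np.zeros(n, dtype=bool)
    for idx in sorted({max(i_l, 0), min(i_r, len(marker_pos) - 1)}):
        d = abs(pos_cm - marker_pos[idx])
        rr = float(ril_recombination(d))
        g = geno[:, idx]
        known = np.isfinite(g)
        t_plus = t_plus * np.where(known, np.where(g > 0, 1 - rr, rr), 0.5)
        t_minus = t_minus * np.where(known, np.where(g > 0, rr, 1 - rr), 0.5)
        any_info |= known
    tot = t_plus + t_minus
    with np.errstate(invalid="ignore", divide="ignore"):
        ex = (t_plus - t_minus) / tot
    ex[~any_info] = np.nan
    return ex, (max(i_l, 0), min(i_r, len(marker_pos) - 1))


def _simple_lod(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """LOD, PVE (%) and slope of y ~ x over finite pairs."""
    keep = np.isfinite(x) & np.isfinite(y)
    n = int(keep.sum())
    if n < 3:
        return 0.0, 0.0, 0.0
    xv, yv = x[keep], y[keep]
    xm, ym = xv.mean(), yv.mean()
    sxx = ((xv - xm) ** 2).sum()
    syy = ((yv - ym) ** 2).sum()
    if sxx <= 1e-12 or syy <= 1e-12:
        return 0.0, 0.0, 0.0
    sxy = ((xv - xm) * (yv - ym)).sum()
    b = sxy / sxx
    rss1 = max(syy - b * sxy, 1e-300)
    lod = 0.5 * n * np.log10(syy / rss1)
    pve = 100.0 * (1.0 - rss1 / syy)
    return float(lod), float(pve), float(b)


class _TraitScanContext:
    """Shared pre-computation for one (dataset, trait) pair."""

    def __init__(self, ds: RilDataset, trait: str, cofactors: dict[str, float] | None):
        self.ds = ds
        self.trait = trait
        y = ds.phenotypes[trait].to_numpy(dtype=float)
        self.keep = np.isfinite(y)
        self.y = y[self.keep]
        self.cofactors = {} if cofactors is None else cofactors
        Ximp = _imputed_genotypes(ds).to_numpy()[self.keep]
        cols = {m: i for i, m in enumerate(ds.genotypes.columns)}
        self.cof_x = {m: Ximp[:, cols[m]] for m in self.cofactors}
        self.y_base = self.y.copy()
        for m, b in self.cofactors.items():
            self.y_base -= b * self.cof_x[m]
        # per-chromosome genotype blocks (with missing retained)
        self.chrom_geno: dict[str, np.ndarray] = {}
        gm = ds.genetic_map
        G = ds.genotypes.to_numpy(dtype=float)[self.keep]
        for chrom in gm.chromosomes:
            idx = [cols[m] for m in gm.names[chrom]]
            self.chrom_geno[chrom] = G[:, idx]

    def adjusted_y(self, flank_markers: set[str]) -> np.ndarray:
        y = self.y_base
        add = [m for m in flank_markers if m in self.cofactors]
        if add:
            y = y.copy()
            for m in add:
                y += self.cofactors[m] * self.cof_x[m]
        return y

    def position(self, chrom: str, pos_cm: float):
        gm = self.ds.genetic_map
        ex, (i_l, i_r) = _expected_x(pos_cm, gm.positions[chrom], self.chrom_geno[chrom])
        flanks = {gm.names[chrom][i_l], gm.names[chrom][i_r]}
        return ex, flanks, (gm.names[chrom][i_l], gm.names[chrom][i_r])


def lod_at(
    ds: RilDataset, trait: str, chrom: str, pos_cm: float,
    cofactors: dict[str, float] | None = None,
) -> float:
    """Additive-scan LOD at an arbitrary map position (used by the grid scan)."""
    ctx = _TraitScanContext(ds, trait, cofactors)
    ex, flanks, _ = ctx.position(chrom, pos_cm)
    lod, _, _ = _simple_lod(ctx.adjusted_y(flanks), ex)
    return lod


def _grid(marker_pos: np.ndarray, step: float) -> np.ndarray:
    lo, hi = marker_pos[0], marker_pos[-1]
    g = np.arange(lo, hi + step / 2, step)
    return np.unique(np.round(np.concatenate([g, marker_pos]), 6))


def additive_scan(
    ds: RilDataset,
    trait: str,
    step: float = 1.0,
    lod_min: float = LOD_SIGNIFICANT,
    merge_radius_cm: float = 10.0,
    cofactors: dict[str, float] | None = None,
    existing_names: set[str] | None = None,
) -> tuple[pd.DataFrame, list[QtlResult]]:
    """Genome-wide additive scan; returns (LOD profile, detected QTLs)."""
    if cofactors is None:
        cofactors = select_cofactors(ds, trait)
    ctx = _TraitScanContext(ds, trait, cofactors)
    gm = ds.genetic_map
    prof_rows = []
    peaks: list[QtlResult] = []
    for chrom in gm.chromosomes:
        mpos = gm.positions[chrom]
        grid = _grid(mpos, step)
        lods = np.zeros(len(grid))
        pves = np.zeros(len(grid))
        effs = np.zeros(len(grid))
        flank_names = []
        for i, pos in enumerate(grid):
            ex, flanks, fnames = ctx.position(chrom, float(pos))
            lods[i], pves[i], effs[i] = _simple_lod(ctx.adjusted_y(flanks), ex)
            flank_names.append(fnames)
        for pos, lod in zip(grid, lods):
            prof_rows.append((trait, chrom, float(pos), float(lod)))
        # local maxima above threshold
        cand = [
            i for i in range(len(grid))
            if lods[i] > lod_min
            and (i == 0 or lods[i] >= lods[i - 1])
            and (i == len(grid) - 1 or lods[i] > lods[i + 1])
        ]
        cand.sort(key=lambda i: -lods[i])
        kept: list[int] = []
        for i in cand:
            if all(abs(grid[i] - grid[j]) > merge_radius_cm for j in kept):
                kept.append(i)
        for i in sorted(kept):
            lo = i
            while lo > 0 and lods[lo - 1] > lods[i] - 1.0:
                lo -= 1
            hi = i
            while hi < len(grid) - 1 and lods[hi + 1] > lods[i] - 1.0:
                hi += 1
            res = QtlResult(
                trait=trait,
                chrom=chrom,
                peak_cm=float(grid[i]),
                lod=float(lods[i]),
                pve=float(pves[i]),
                effect=float(effs[i]),
                ci_lo_cm=float(grid[lo]),
                ci_hi_cm=float(grid[hi]),
                left_marker=flank_names[i][0],
                right_marker=flank_names[i][1],
                significance=classify_significance(float(lods[i])) or "",
            )
            res.validate()
            peaks.append(res)
    peaks.sort(key=lambda r: (r.chrom, r.peak_cm))
    names = set() if existing_names is None else existing_names
    for r in peaks:
        r.name = name_qtl(r.trait, r.chrom, names)
    profile = pd.DataFrame(prof_rows, columns=["trait", "chrom", "cM", "LOD"])
    return profile, peaks


def epistasis_scan(
    ds: RilDataset,
    trait: str,
    step: float = 5.0,
    lod_min: float = 5.0,
    pve_min: float = 5.0,
    min_separation_cm: float = 20.0,
    merge_radius_cm: float = 20.0,
    cofactors: dict[str, float] | None = None,
) -> list[EpistaticPair]:
    """Digenic epistasis scan over a coarse two-locus grid."""
    if cofactors is None:
        cofactors = select_cofactors(ds, trait)
    ctx = _TraitScanContext(ds, trait, cofactors)
    gm = ds.genetic_map
    # precompute per grid position
    positions: list[tuple[str, float]] = []
    ex_cols: list[np.ndarray] = []
    flank_sets: list[set[str]] = []
    for chrom in gm.chromosomes:
        mpos = gm.positions[chrom]
        for pos in np.arange(mpos[0], mpos[-1] + step / 2, step):
            ex, flanks, _ = ctx.position(chrom, float(pos))
            positions.append((chrom, float(pos)))
            ex_cols.append(ex)
            flank_sets.append(flanks)
    n_pos = len(positions)
    found: list[EpistaticPair] = []
    ones = np.ones(len(ctx.y))
    for i in range(n_pos):
        ci, pi = positions[i]
        xi = ex_cols[i]
        for j in range(i + 1, n_pos):
            cj, pj = positions[j]
            if ci == cj and abs(pi - pj) < min_separation_cm:
                continue
            xj = ex_cols[j]
            y = ctx.adjusted_y(flank_sets[i] | flank_sets[j])
            keep = np.isfinite(xi) & np.isfinite(xj) & np.isfinite(y)
            n = int(keep.sum())
            if n < 5:
                continue
            x1, x2, yv = xi[keep], xj[keep], y[keep]
            inter = x1 * x2
            Xa = np.column_stack([ones[keep], x1, x2])
            Xf = np.column_stack([Xa, inter])
            ca, rss_a, *_ = np.linalg.lstsq(Xa, yv, rcond=None)
            cf, rss_f, *_ = np.linalg.lstsq(Xf, yv, rcond=None)
            rss_a = float(((yv - Xa @ ca) ** 2).sum())
            rss_f = float(((yv - Xf @ cf) ** 2).sum())
            if rss_f <= 1e-300:
                continue
            lod = 0.5 * n * np.log10(rss_a / rss_f)
            ss_tot = float(((yv - yv.mean()) ** 2).sum())
            pve = 100.0 * (rss_a - rss_f) / ss_tot if ss_tot > 0 else 0.0
            if lod >= lod_min and pve >= pve_min:
                found.append(
                    EpistaticPair(
                        trait=trait, chrom_a=ci, pos_a_cm=pi, chrom_b=cj, pos_b_cm=pj,
                        lod=float(lod), pve=float(pve), effect=float(cf[3]),
                    )
                )
    # merge overlapping pairs to the local 2-D maximum
    found.sort(key=lambda p: -p.lod)
    kept: list[EpistaticPair] = []
    for p in found:
        clash = any(
            {p.chrom_a, p.chrom_b} == {q.chrom_a, q.chrom_b}
            and _pair_close(p, q, merge_radius_cm)
            for q in kept
        )
        if not clash:
            kept.append(p)
    kept.sort(key=lambda p: (p.chrom_a, p.pos_a_cm, p.chrom_b, p.pos_b_cm))
    return kept


def _pair_close(p: EpistaticPair, q: EpistaticPair, radius: float) -> bool:
    direct = (
        p.chrom_a == q.chrom_a and p.chrom_b == q.chrom_b
        and abs(p.pos_a_cm - q.pos_a_cm) <= radius and abs(p.pos_b_cm - q.pos_b_cm) <= radius
    )
    swapped = (
        p.chrom_a == q.chrom_b and p.chrom_b == q.chrom_a
        and abs(p.pos_a_cm - q.pos_b_cm) <= radius and abs(p.pos_b_cm - q.pos_a_cm) <= radius
    )
    return direct or swapped


def scan_all_traits(
    ds: RilDataset, traits: list[str] | None = None, step: float = 1.0, **kwargs
) -> tuple[pd.DataFrame, list[QtlResult]]:
    """Additive scans for several traits with a shared QTL-name registry."""
    traits = ds.traits if traits is None else traits
    all_profiles, all_results = [], []
    names: set[str] = set()
    for trait in traits:
        prof, res = additive_scan(ds, trait, step=step, existing_names=names, **kwargs)
        all_profiles.append(prof)
        all_results.extend(res)
    return pd.concat(all_profiles, ignore_index=True), all_results


def results_to_frame(results: list[QtlResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trait": r.trait, "qtl": r.name, "chrom": r.chrom, "peak_cM": r.peak_cm,
                "LOD": r.lod, "PVE": r.pve, "effect": r.effect,
                "ci_lo_cM": r.ci_lo_cm, "ci_hi_cM": r.ci_hi_cm,
                "left_marker": r.left_marker, "right_marker": r.right_marker,
                "significance": r.significance,
            }
            for r in results
        ],
        columns=[
            "trait", "qtl", "chrom", "peak_cM", "LOD", "PVE", "effect",
            "ci_lo_cM", "ci_hi_cM", "left_marker", "right_marker", "significance",
        ],
    )


def epistasis_to_frame(pairs: list[EpistaticPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trait": p.trait, "chrom_a": p.chrom_a, "pos_a_cM": p.pos_a_cm,
                "chrom_b": p.chrom_b, "pos_b_cM": p.pos_b_cm,
                "LOD": p.lod, "PVE": p.pve, "effect": p.effect,
            }
            for p in pairs
        ],
        columns=["trait", "chrom_a", "pos_a_cM", "chrom_b", "pos_b_cM", "LOD", "PVE", "effect"],
    )
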