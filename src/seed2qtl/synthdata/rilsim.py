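"""Simulation of a biparental recombinant-inbred-line (RIL) population.

Genotypes follow a two-state Markov chain along each chromosome.  Map
distances convert to single-meiosis recombination fractions with the Haldane
function (no interference), r = (1 - exp(-2d/100)) / 2 for d in cM, and the
chain switches parental type between adjacent markers with the selfed-RIL
effective frequency R = 2r / (1 + 2r).  Marginal allele frequencies are 1/2,
as expected for a RIL population without segregation distortion.

Phenotypes are linear in +/-1-coded QTL genotypes with optional digenic
interaction terms and Gaussian residual noise; the realized per-term variance
share (PVE) is reported alongside the simulated values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "RilSimSpec",
    "haldane_r",
    "ril_recombination",
    "default_map",
    "simulate_ril_genotypes",
    "simulate_phenotypes",
]

WHEAT_CHROMOSOMES = tuple(f"{n}{g}" for n in range(1, 8) for g in "ABD")


def haldane_r(d_cm) -> np.ndarray:
    """Haldane map function: recombination fraction for a distance in cM."""
    return (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0)) / 2.0


def ril_recombination(d_cm) -> np.ndarray:
    """Effective recombination frequency between RIL genotypes, R = 2r/(1+2r)."""
    r = haldane_r(d_cm)
    return 2.0 * r / (1.0 + 2.0 * r)


@dataclass
class GeneticMap:
    """Ordered marker positions per chromosome.

    ``positions`` maps chromosome id -> strictly increasing cM array;
    marker names default to ``<chrom>_m<i>``.
    """

    positions: dict[str, np.ndarray]
    names: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos, dtype=float)
            if np.any(np.diff(pos) <= 0) and len(pos) > 1:
                if np.any(np.diff(pos) < 0):
                    raise ValueError(f"marker positions not increasing on {chrom}")
            self.positions[chrom] = pos
            if chrom not in self.names:
                self.names[chrom] = [f"{chrom}_m{i}" for i in range(len(pos))]

    @property
    def chromosomes(self) -> list[str]:
        return list(self.positions)

    @property
    def n_markers(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def marker_names(self) -> list[str]:
        return [m for c in self.positions for m in self.names[c]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.positions:
            for name, cm in zip(self.names[chrom], self.positions[chrom]):
                rows.append((chrom, name, float(cm)))
        return pd.DataFrame(rows, columns=["chrom", "marker", "cM"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        positions, names = {}, {}
        for chrom, grp in df.groupby("chrom", sort=False):
            positions[chrom] = grp["cM"].to_numpy(dtype=float)
            names[chrom] = grp["marker"].tolist()
        return cls(positions=positions, names=names)


def default_map(
    n_chromosomes: int = 21, spacing_cm: float = 5.0, length_cm: float = 120.0
) -> GeneticMap:
    """Uniform map over (a prefix of) the 21 wheat chromosomes."""
    chroms = WHEAT_CHROMOSOMES[:n_chromosomes]
    pos = np.arange(0.0, length_cm + spacing_cm / 2, spacing_cm)
    return GeneticMap(positions={c: pos.copy() for c in chroms})


@dataclass
class RilSimSpec:
    """Parameters of one simulated RIL study.

    ``qtl_spec`` lists additive loci as (chrom, cM, effect); ``epi_spec``
    lists digenic interactions as ((chromA, cMA), (chromB, cMB), effect).
    Effects are in phenotype units per +/-1 genotype code.
    """

    genetic_map: GeneticMap
    n_lines: int = 114
    qtl_spec: list[tuple[str, float, float]] = field(default_factory=list)
    epi_spec: list[tuple[tuple[str, float], tuple[str, float], float]] = field(default_factory=list)
    residual_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_lines < 2:
            raise ValueError("need at least 2 lines")
        if self.residual_sd < 0:
            raise ValueError("residual sd must be non-negative")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing rate must be in [0, 1)")
        for chrom, cm, _ in self.qtl_spec:
            self._check_locus(chrom, cm)
        for (ca, pa), (cb, pb), _ in self.epi_spec:
            self._check_locus(ca, pa)
            self._check_locus(cb, pb)

    def _check_locus(self, chrom: str, cm: float) -> None:
        pos = self.genetic_map.positions.get(chrom)
        if pos is None:
            raise ValueError(f"QTL chromosome {chrom!r} not on the map")
        if not (pos[0] <= cm <= pos[-1]):
            raise ValueError(f"QTL at {chrom}:{cm} cM lies outside the map extent")


def simulate_ril_genotypes(spec: RilSimSpec) -> pd.DataFrame:
    """Simulate the lines x markers genotype matrix, coded +1/-1 with NaN missing.

    +1 is conventionally the first-parent (Opata-type) allele.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    gm = spec.genetic_map
    n = spec.n_lines
    cols = []
    for chrom in gm.chromosomes:
        pos = gm.positions[chrom]
        m = len(pos)
        g = np.empty((n, m), dtype=float)
        g[:, 0] = rng.choice([-1.0, 1.0], size=n)
        if m > 1:
            rr = ril_recombination(np.diff(pos))
            switch = rng.random((n, m - 1)) < rr[None, :]
            for j in range(1, m):
                g[:, j] = np.where(switch[:, j - 1], -g[:, j - 1], g[:, j - 1])
        cols.append(g)
    geno = np.concatenate(cols, axis=1)
    if spec.missing_rate > 0:
        geno[rng.random(geno.shape) < spec.missing_rate] = np.nan
    lines = [f"RIL_{i + 1:03d}" for i in range(n)]
    return pd.DataFrame(geno, index=lines, columns=gm.marker_names())


def _locus_column(geno: pd.DataFrame, gm: GeneticMap, chrom: str, cm: float) -> np.ndarray:
    """Genotype codes at the marker nearest to (chrom, cm); NaN treated as 0."""
    pos = gm.positions[chrom]
    j = int(np.argmin(np.abs(pos - cm)))
    x = geno[gm.names[chrom][j]].to_numpy(dtype=float)
    return np.nan_to_num(x, nan=0.0)


def simulate_phenotypes(
    geno: pd.DataFrame, spec: RilSimSpec, trait: str = "trait"
) -> tuple[pd.Series, pd.DataFrame]:
    """Simulate one trait; returns (phenotype, ground-truth effect table).

    y = sum_i a_i x_i + sum_j e_j x1_j x2_j + N(0, sd^2), with x coded +/-1.
    The truth table reports each term's realized PVE, var(term) / var(y).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 104729)  # distinct stream from genotypes
    gm = spec.genetic_map
    n = len(geno)
    y = np.zeros(n)
    terms: list[tuple[str, str, float, np.ndarray]] = []
    for chrom, cm, eff in spec.qtl_spec:
        x = _locus_column(geno, gm, chrom, cm)
        y += eff * x
        terms.append(("additive", f"{chrom}:{cm}", eff, eff * x))
    for (ca, pa), (cb, pb), eff in spec.epi_spec:
        x12 = _locus_column(geno, gm, ca, pa) * _locus_column(geno, gm, cb, pb)
        y += eff * x12
        terms.append(("epistatic", f"{ca}:{pa} x {cb}:{pb}", eff, eff * x12))
    if spec.residual_sd > 0:
        y = y + rng.normal(0.0, spec.residual_sd, n)
    var_y = float(np.var(y)) if np.var(y) > 0 else np.nan
    truth = pd.DataFrame(
        [
            {
                "trait": trait,
                "kind": kind,
                "locus": locus,
                "effect": eff,
                "realized_pve": 100.0 * float(np.var(contrib)) / var_y if var_y == var_y else np.nan,
            }
            for kind, locus, eff, contrib in terms
        ],
        columns=["trait", "kind", "locus", "effect", "realized_pve"],
    )
    return pd.Series(y, index=geno.index, name=trait), truth


def pve_to_effect(pve: float, residual_sd: float = 1.0) -> float:
    """Additive effect size giving the requested PVE with var(x) = 1.

    PVE = a^2 / (a^2 + sd^2)  =>  a = sd * sqrt(PVE / (1 - PVE)).
    """
    if not (0.0 <= pve < 1.0):
        raise ValueError("pve must be in [0, 1)")
    return residual_sd * float(np.sqrt(pve / (1.0 - pve)))
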