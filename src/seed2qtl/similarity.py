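"""Trait similarity by QTL-location overlap: Ochiai index and UPGMA tree.

Each trait is reduced to the set of loci (chromosome + peak position) its
QTLs map to; for two traits with locus sets A and B the Ochiai index is

    S(A, B) = |A ∩ B| / sqrt(|A| * |B|),

1 for identical sets, 0 for disjoint ones (and, by convention, whenever
either set is empty).  Traits are then clustered agglomeratively on the
distance d = 1 - S with UPGMA (average) linkage; ties are made deterministic
by presenting traits in lexicographic name order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "LocusKey",
    "build_locus_sets",
    "ochiai",
    "ochiai_matrix",
    "cluster_traits",
    "to_newick",
]


@dataclass(frozen=True)
class LocusKey:
    chrom: str
    pos_cm: float  # canonical (rounded/unified) peak position


def build_locus_sets(
    qtl_results: pd.DataFrame,
    tolerance_cm: float = 0.0,
    decimals: int = 3,
) -> dict[str, set[LocusKey]]:
    """Per-trait sets of canonical locus keys from a scan-results table.

    Expects columns ``trait``, ``chrom``, ``peak_cM``.  Peaks are rounded to
    ``decimals``; with ``tolerance_cm > 0``, peaks on the same chromosome
    closer than the tolerance are unified (union-find) to one canonical key
    (the smallest member position).
    """
    df = qtl_results[["trait", "chrom", "peak_cM"]].copy()
    df["peak_cM"] = df["peak_cM"].astype(float).round(decimals)
    canon: dict[tuple[str, float], tuple[str, float]] = {}
    if tolerance_cm > 0:
        parent: dict[tuple[str, float], tuple[str, float]] = {}

        def find(k):
            while parent[k] != k:
                parent[k] = parent[parent[k]]
                k = parent[k]
            return k

        keys = sorted({(c, p) for c, p in zip(df["chrom"], df["peak_cM"])})
        for k in keys:
            parent[k] = k
        for (c1, p1), (c2, p2) in zip(keys, keys[1:]):
            if c1 == c2 and abs(p2 - p1) <= tolerance_cm:
                parent[find((c2, p2))] = find((c1, p1))
        canon = {k: find(k) for k in keys}
    out: dict[str, set[LocusKey]] = {t: set() for t in df["trait"].unique()}
    for t, c, p in df.itertuples(index=False):
        key = canon.get((c, p), (c, p))
        out[t].add(LocusKey(chrom=key[0], pos_cm=float(key[1])))
    return out


def ochiai(set_a: set, set_b: set) -> float:
    """|A∩B| / sqrt(|A|·|B|); 0 when either set is empty."""
    if not set_a or not set_b:
        return 0.0
    return len(set_a & set_b) / float(np.sqrt(len(set_a) * len(set_b)))


def ochiai_matrix(locus_sets: dict[str, set], traits: list[str] | None = None) -> pd.DataFrame:
    """Symmetric trait x trait Ochiai matrix (diagonal 1 for non-empty sets)."""
    if traits is None:
        traits = sorted(locus_sets)
    n = len(traits)
    m = np.zeros((n, n))
    for i, a in enumerate(traits):
        for j in range(i, n):
            v = ochiai(locus_sets.get(a, set()), locus_sets.get(traits[j], set()))
            m[i, j] = m[j, i] = v
        if locus_sets.get(a):
            m[i, i] = 1.0
    return pd.DataFrame(m, index=traits, columns=traits)


def cluster_traits(similarity: pd.DataFrame, method: str = "average"):
    """UPGMA tree on d = 1 - similarity; returns (linkage, leaf order).

    Traits with empty locus sets (zero diagonal) attach at maximal distance 1.
    """
    traits = sorted(similarity.index)
    sim = similarity.loc[traits, traits].to_numpy(dtype=float)
    np.fill_diagonal(sim, 1.0)
    dist = np.clip(1.0 - sim, 0.0, 1.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    order = [traits[i] for i in hierarchy.leaves_list(z)]
    return z, traits, order


def to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Newick serialization with branch lengths from merge heights."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, h, _ = linkage[i - n]
        a, b = int(a), int(b)
        return f"({node(a)}:{h - heights[a]:.6g},{node(b)}:{h - heights[b]:.6g})"

    for k, (_, _, h, _) in enumerate(linkage):
        heights[n + k] = float(h)
    return node(n + len(linkage) - 1) + ";"
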