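"""Toy annotation / expression / orthology fixtures with planted candidates.

The gene-prioritization stage consumes five tables (marker physical
coordinates, GFF3 gene annotation with a confidence attribute, a TPM
expression matrix with tissue labels, a gene -> KEGG-orthogroup table, and
target KO sets for size/shape and coat-color traits).  This module fabricates
a mutually consistent set of those tables around a list of planted candidate
genes, plus decoy genes that each fail exactly one filter of the cascade
(outside the interval; low confidence; TPM < 1 in seed tissue; KO not in the
target set), so the expected output of the cascade is known by construction.

Genetic-to-physical convention used by the fixtures: 1 cM = 1 Mbp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["QtlPlan", "PriorFixture", "make_prior_fixture", "COLOR_PATHWAYS"]

# KEGG pathways of pigment biosynthesis and precursors used for coat color.
COLOR_PATHWAYS = {
    "map00380": "Tryptophan metabolism",
    "map00900": "Terpenoid backbone biosynthesis",
    "map00906": "Carotenoid biosynthesis",
    "map00940": "Phenylpropanoid biosynthesis",
    "map00941": "Flavonoid biosynthesis",
    "map00942": "Anthocyanin biosynthesis",
    "map00943": "Isoflavonoid biosynthesis",
    "map00944": "Flavone and flavonol biosynthesis",
}

BP_PER_CM = 1_000_000


@dataclass
class QtlPlan:
    """One QTL to build fixtures around."""

    name: str                 # e.g. "Q.sA-3A"
    trait: str                # e.g. "sA"
    chrom: str                # e.g. "3A"
    peak_cm: float
    trait_class: str          # "size_shape" or "color"
    n_planted: int = 1
    flank_halfwidth_cm: float = 5.0
    wrong_chromosome_marker: bool = False  # plant a flank on the wrong chromosome

    def __post_init__(self):
        if self.trait_class not in ("size_shape", "color"):
            raise ValueError("trait_class must be 'size_shape' or 'color'")
        if self.n_planted < 0:
            raise ValueError("n_planted must be >= 0")


@dataclass
class PriorFixture:
    """In-memory fixture tables plus the planted-truth manifest."""

    marker_coords: pd.DataFrame     # marker, chrom, start, end
    annotation_gff3: str            # GFF3 text
    expression: pd.DataFrame        # gene, sample, tissue, tpm
    gene2ko: pd.DataFrame           # gene, ko, ko_description, ec, pathway, pathway_description
    target_ko_size: pd.DataFrame    # ko, description
    target_ko_color: pd.DataFrame   # ko, description, pathway, pathway_description
    qtl_flanks: pd.DataFrame        # qtl, trait, chrom, peak_cm, trait_class, left_marker, right_marker
    planted: list[str] = field(default_factory=list)
    planted_by_qtl: dict[str, list[str]] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for key, df in [
            ("marker_coords", self.marker_coords),
            ("expression", self.expression),
            ("gene2ko", self.gene2ko),
            ("target_ko_size", self.target_ko_size),
            ("target_ko_color", self.target_ko_color),
            ("qtl_flanks", self.qtl_flanks),
        ]:
            p = outdir / f"{key}.tsv"
            df.to_csv(p, sep="\t", index=False)
            paths[key] = p
        p = outdir / "annotation.gff3"
        p.write_text(self.annotation_gff3)
        paths["annotation"] = p
        p = outdir / "planted_candidates.txt"
        p.write_text("\n".join(self.planted) + ("\n" if self.planted else ""))
        paths["planted"] = p
        return paths


def _gene_id(chrom: str, serial: int) -> str:
    return f"TraesSYN{chrom}01G{serial:05d}"


def make_prior_fixture(plans: list[QtlPlan], seed: int = 0) -> PriorFixture:
    """Build consistent fixture tables around the planted QTL plans."""
    rng = np.random.default_rng(seed)
    markers, gff, expr, g2k, flanks = [], [], [], [], []
    planted: list[str] = []
    planted_by_qtl: dict[str, list[str]] = {}
    chrom_extent: dict[str, int] = {}

    size_kos = [(f"K1{j:04d}", f"seed-size regulator family {j}") for j in range(1, 7)]
    color_kos = []
    for j, (pid, pdesc) in enumerate(COLOR_PATHWAYS.items(), start=1):
        for k in range(2):
            color_kos.append((f"K2{j:02d}{k:02d}", f"{pdesc} enzyme {k + 1}", pid, pdesc))
    offtarget_ko = ("K99999", "unrelated housekeeping enzyme")

    serial = 1
    for plan in plans:
        qtl_planted: list[str] = []
        lo_cm = plan.peak_cm - plan.flank_halfwidth_cm
        hi_cm = plan.peak_cm + plan.flank_halfwidth_cm
        lo_bp = int(round(max(lo_cm, 0.0) * BP_PER_CM)) + 1
        hi_bp = int(round(hi_cm * BP_PER_CM))
        lmark, rmark = f"m_{plan.name}_L", f"m_{plan.name}_R"
        lchrom = "9Z" if plan.wrong_chromosome_marker else plan.chrom
        markers.append((lmark, lchrom, lo_bp, lo_bp + 99))
        markers.append((rmark, plan.chrom, hi_bp - 99, hi_bp))
        flanks.append(
            (plan.name, plan.trait, plan.chrom, plan.peak_cm, plan.trait_class, lmark, rmark)
        )
        width = hi_bp - lo_bp

        def add_gene(pos_frac, confidence, tpm_seed, ko_entry, *, outside=False):
            nonlocal serial
            gid = _gene_id(plan.chrom, serial)
            serial += 1
            if outside:
                start = hi_bp + 10 * BP_PER_CM + int(pos_frac * width)
            else:
                start = lo_bp + int(pos_frac * (width - 3000))
            end = start + 2999
            attrs = f"ID=gene:{gid};biotype=protein_coding;confidence={confidence}"
            gff.append(f"{plan.chrom}\tsynth\tgene\t{start}\t{end}\t.\t+\t.\t{attrs}")
            chrom_extent[plan.chrom] = max(chrom_extent.get(plan.chrom, 0), end + BP_PER_CM)
            expr.append((gid, "seed_s1", "seed", round(float(tpm_seed), 3)))
            expr.append((gid, "seed_s2", "seed", round(float(max(tpm_seed * 0.8, 0.0)), 3)))
            expr.append((gid, "leaf_s1", "leaf", round(float(rng.uniform(0, 30)), 3)))
            if ko_entry is not None:
                if len(ko_entry) == 4:
                    ko, desc, pid, pdesc = ko_entry
                    ec = f"EC:1.14.{rng.integers(1, 20)}.{rng.integers(1, 20)}"
                else:
                    ko, desc = ko_entry
                    pid, pdesc, ec = "", "", f"EC:2.3.{rng.integers(1, 20)}.{rng.integers(1, 20)}"
                g2k.append((gid, ko, desc, ec, pid, pdesc))
            return gid

        target_pool = color_kos if plan.trait_class == "color" else size_kos
        for i in range(plan.n_planted):
            ko_entry = target_pool[int(rng.integers(len(target_pool)))]
            gid = add_gene(rng.uniform(0.1, 0.9), "high", rng.uniform(2.0, 50.0), ko_entry)
            qtl_planted.append(gid)
        # decoys: each fails exactly one filter of the cascade
        ko_entry = target_pool[int(rng.integers(len(target_pool)))]
        add_gene(rng.uniform(0, 1), "high", rng.uniform(2.0, 50.0), ko_entry, outside=True)
        ko_entry = target_pool[int(rng.integers(len(target_pool)))]
        add_gene(rng.uniform(0.1, 0.9), "low", rng.uniform(2.0, 50.0), ko_entry)
        add_gene(rng.uniform(0.1, 0.9), "high", rng.uniform(2.0, 50.0), offtarget_ko)
        add_gene(rng.uniform(0.1, 0.9), "high", rng.uniform(5.0, 50.0), None)  # no KO at all
        if plan.trait_class == "color":
            ko_entry = target_pool[int(rng.integers(len(target_pool)))]
            add_gene(rng.uniform(0.1, 0.9), "high", rng.uniform(0.0, 0.5), ko_entry)
        planted.extend(qtl_planted)
        planted_by_qtl[plan.name] = qtl_planted

    header = ["##gff-version 3"]
    for chrom, ext in sorted(chrom_extent.items()):
        header.append(f"##sequence-region {chrom} 1 {ext}")
    gff3_text = "\n".join(header + gff) + "\n"

    return PriorFixture(
        marker_coords=pd.DataFrame(markers, columns=["marker", "chrom", "start", "end"]),
        annotation_gff3=gff3_text,
        expression=pd.DataFrame(expr, columns=["gene", "sample", "tissue", "tpm"]),
        gene2ko=pd.DataFrame(
            g2k, columns=["gene", "ko", "ko_description", "ec", "pathway", "pathway_description"]
        ),
        target_ko_size=pd.DataFrame(size_kos, columns=["ko", "description"]),
        target_ko_color=pd.DataFrame(
            color_kos, columns=["ko", "description", "pathway", "pathway_description"]
        ),
        qtl_flanks=pd.DataFrame(
            flanks,
            columns=["qtl", "trait", "chrom", "peak_cm", "trait_class", "left_marker", "right_marker"],
        ),
        planted=planted,
        planted_by_qtl=planted_by_qtl,
    )
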