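"""Candidate-gene prioritization inside significant QTL intervals.

Cascade, per QTL with LOD > 3 (highly significant):

1. ``qtl_to_interval`` — span the physical coordinates of the two flanking
   markers; a QTL whose marker maps to a different chromosome than the QTL's
   genetic chromosome is skipped with a logged reason.
2. ``genes_in_interval`` — high-confidence annotated genes overlapping the
   interval by at least 1 bp (GFF3 1-based inclusive coordinates).
3. ``filter_by_expression`` — for coat-color traits only, keep genes with
   TPM >= 1 in at least one seed-tissue sample (genes absent from the
   expression table count as not expressed).
4. ``match_orthogroups`` — keep genes carrying at least one KEGG orthogroup
   from the target set of their trait class (size/shape or color).

Marker physical coordinates and gene -> KO assignments are consumed as input
tables; upstream sequence alignment / KO-assignment services are out of scope.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd

from .phenotyping.traits import SIZE_SHAPE_TRAITS

__all__ = [
    "PhysicalInterval",
    "IntervalError",
    "trait_class",
    "qtl_to_interval",
    "load_gene_annotation",
    "genes_in_interval",
    "filter_by_expression",
    "match_orthogroups",
    "prioritize_candidates",
]

CANDIDATE_COLUMNS = [
    "qtl", "trait", "trait_class", "chrom", "interval_start", "interval_end",
    "gene", "ko", "ko_description", "ec", "pathway", "pathway_description",
]


class IntervalError(ValueError):
    """A QTL whose physical interval cannot be established."""


@dataclass
class PhysicalInterval:
    chrom: str
    start: int          # bp, 1-based inclusive
    end: int
    qtl_names: list[str] = field(default_factory=list)
    flanking_markers: tuple[str, str] = ("", "")

    def validate(self) -> None:
        if self.start > self.end:
            raise ValueError("interval start exceeds end")


def trait_class(trait: str) -> str:
    """'size_shape' for the 7 morphometry traits, 'color' for the 48 others."""
    return "size_shape" if trait in SIZE_SHAPE_TRAITS else "color"


def qtl_to_interval(qtl_row, marker_coords: pd.DataFrame) -> PhysicalInterval:
    """Physical interval spanned by a QTL's flanking markers.

    ``qtl_row`` needs fields qtl, chrom, left_marker, right_marker.  Raises
    :class:`IntervalError` when a marker is absent from the coordinate table
    or maps to a chromosome other than the QTL's.
    """
    coords = marker_coords.set_index("marker") if marker_coords.index.name != "marker" else marker_coords
    starts, ends = [], []
    for m in (qtl_row["left_marker"], qtl_row["right_marker"]):
        if m not in coords.index:
            raise IntervalError(f"marker {m} has no physical coordinates")
        row = coords.loc[m]
        if str(row["chrom"]) != str(qtl_row["chrom"]):
            raise IntervalError(
                f"marker {m} maps to chromosome {row['chrom']}, "
                f"not the QTL chromosome {qtl_row['chrom']}"
            )
        starts.append(int(row["start"]))
        ends.append(int(row["end"]))
    iv = PhysicalInterval(
        chrom=str(qtl_row["chrom"]),
        start=min(starts),
        end=max(ends),
        qtl_names=[qtl_row["qtl"]],
        flanking_markers=(qtl_row["left_marker"], qtl_row["right_marker"]),
    )
    iv.validate()
    return iv


def load_gene_annotation(source: str | Path, from_string: bool = False) -> pd.DataFrame:
    """Parse GFF3 gene records into (gene, chrom, start, end, confidence)."""
    if from_string:
        with tempfile.NamedTemporaryFile("w", suffix=".gff3", delete=False) as fh:
            fh.write(str(source))
            path = fh.name
    else:
        path = str(source)
    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", id_spec={"gene": "ID"},
    )
    rows = []
    for g in db.features_of_type("gene"):
        gid = g.id.split(":", 1)[-1]
        conf = (g.attributes.get("confidence") or ["high"])[0]
        rows.append((gid, g.seqid, int(g.start), int(g.end), conf.lower()))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "confidence"])


def genes_in_interval(
    annotation: pd.DataFrame, interval: PhysicalInterval, high_confidence_only: bool = True
) -> list[str]:
    """Gene ids overlapping the interval by >= 1 bp (1-based inclusive)."""
    sel = annotation[
        (annotation["chrom"].astype(str) == interval.chrom)
        & (annotation["start"] <= interval.end)
        & (annotation["end"] >= interval.start)
    ]
    if high_confidence_only:
        sel = sel[sel["confidence"] == "high"]
    return sorted(sel["gene"].unique())


def filter_by_expression(
    genes: list[str],
    expression: pd.DataFrame,
    tissue_label: str = "seed",
    tpm_min: float = 1.0,
    agg: str = "max",
) -> list[str]:
    """Genes with TPM >= tpm_min in at least one ``tissue_label`` sample.

    ``agg`` aggregates a gene's TPM across seed samples ('max' keeps a gene
    expressed in any sample).  Genes missing from the table are dropped.
    """
    tissue = expression[expression["tissue"].astype(str).str.lower() == tissue_label.lower()]
    agg_tpm = tissue.groupby("gene")["tpm"].agg(agg)
    return sorted(g for g in genes if float(agg_tpm.get(g, 0.0)) >= tpm_min)


def match_orthogroups(
    genes: list[str], gene2ko: pd.DataFrame, target_kos: set[str]
) -> pd.DataFrame:
    """Rows (gene, ko, annotations) for genes with >= 1 KO in the target set."""
    sel = gene2ko[gene2ko["gene"].isin(genes) & gene2ko["ko"].isin(target_kos)]
    return sel.drop_duplicates(subset=["gene", "ko"]).sort_values(["gene", "ko"]).reset_index(drop=True)


def prioritize_candidates(
    qtl_table: pd.DataFrame,
    marker_coords: pd.DataFrame,
    annotation: pd.DataFrame,
    expression: pd.DataFrame,
    gene2ko: pd.DataFrame,
    target_ko_size: set[str],
    target_ko_color: set[str],
    lod_min: float = 3.0,
    tpm_min: float = 1.0,
    tissue_label: str = "seed",
    expression_filter_classes: tuple[str, ...] = ("color",),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full cascade; returns (candidate table, skipped-QTL log).

    ``qtl_table`` needs columns qtl, trait, chrom, left_marker, right_marker
    and, when present, LOD (rows with LOD <= ``lod_min`` are excluded first).
    A ``trait_class`` column is honored if present, otherwise derived from the
    trait name.
    """
    df = qtl_table.copy()
    if "LOD" in df.columns:
        df = df[df["LOD"] > lod_min]
    if "trait_class" not in df.columns:
        df["trait_class"] = df["trait"].map(trait_class)
    out_rows = []
    skipped = []
    for _, row in df.iterrows():
        try:
            iv = qtl_to_interval(row, marker_coords)
        except IntervalError as e:
            skipped.append({"qtl": row["qtl"], "reason": str(e)})
            continue
        genes = genes_in_interval(annotation, iv)
        if row["trait_class"] in expression_filter_classes:
            genes = filter_by_expression(
                genes, expression, tissue_label=tissue_label, tpm_min=tpm_min
            )
        targets = target_ko_color if row["trait_class"] == "color" else target_ko_size
        hits = match_orthogroups(genes, gene2ko, targets)
        for _, h in hits.iterrows():
            out_rows.append(
                {
                    "qtl": row["qtl"],
                    "trait": row["trait"],
                    "trait_class": row["trait_class"],
                    "chrom": iv.chrom,
                    "interval_start": iv.start,
                    "interval_end": iv.end,
                    "gene": h["gene"],
                    "ko": h["ko"],
                    "ko_description": h.get("ko_description", ""),
                    "ec": h.get("ec", ""),
                    "pathway": h.get("pathway", ""),
                    "pathway_description": h.get("pathway_description", ""),
                }
            )
    candidates = pd.DataFrame(out_rows, columns=CANDIDATE_COLUMNS)
    skipped_df = pd.DataFrame(skipped, columns=["qtl", "reason"])
    return candidates, skipped_df
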