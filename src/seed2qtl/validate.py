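"""Schema validation of input tables; reports problems with line numbers."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["validate_inputs", "validate_map", "validate_genotypes", "validate_gff3"]

VALID_GENO_CODES = {"A", "B", "NA", "2", "0", "-1", ""}


def validate_map(path: str | Path) -> list[dict]:
    issues = []
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "marker", "cM"}
    if not need.issubset(df.columns):
        return [{"file": str(path), "line": 1, "message": f"map needs columns {sorted(need)}"}]
    for chrom, grp in df.groupby("chrom", sort=False):
        cm = grp["cM"].to_numpy()
        bad = (cm[1:] < cm[:-1]).nonzero()[0]
        for i in bad:
            issues.append(
                {
                    "file": str(path),
                    "line": int(grp.index[i + 1]) + 2,  # +header +0-base
                    "message": f"cM not sorted on chromosome {chrom}",
                }
            )
    return issues


def validate_genotypes(path: str | Path) -> list[dict]:
    issues = []
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    for i, (line_id, row) in enumerate(df.iterrows()):
        bad = {str(v).strip() for v in row if str(v).strip() not in VALID_GENO_CODES and v == v}
        if bad:
            issues.append(
                {
                    "file": str(path),
                    "line": i + 2,
                    "message": f"line {line_id}: RIL matrix admits only A/B/NA codes, found {sorted(bad)}",
                }
            )
    return issues


def validate_phenotypes(path: str | Path) -> list[dict]:
    issues = []
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            issues.append(
                {"file": str(path), "line": 1, "message": f"phenotype column {col} is not numeric"}
            )
    return issues


def validate_gff3(path: str | Path) -> list[dict]:
    issues = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            issues.append(
                {"file": str(path), "line": i, "message": f"GFF3 row has {len(parts)} columns, expected 9"}
            )
            continue
        try:
            start, end = int(parts[3]), int(parts[4])
            if start > end or start < 1:
                issues.append(
                    {"file": str(path), "line": i, "message": "invalid 1-based feature coordinates"}
                )
        except ValueError:
            issues.append({"file": str(path), "line": i, "message": "non-integer coordinates"})
    return issues


_VALIDATORS = {
    "map": validate_map,
    "genotypes": validate_genotypes,
    "phenotypes": validate_phenotypes,
    "annotation": validate_gff3,
}


def validate_inputs(paths: dict[str, str | Path]) -> list[dict]:
    """Validate each named input; an empty report means all inputs are clean.

    Keys of ``paths`` select the schema: map, genotypes, phenotypes, annotation.
    Validation never mutates inputs.
    """
    report = []
    for kind, path in paths.items():
        checker = _VALIDATORS.get(kind)
        if checker is None:
            report.append({"file": str(path), "line": 0, "message": f"no validator for kind {kind!r}"})
            continue
        if not Path(path).exists():
            report.append({"file": str(path), "line": 0, "message": "file not found"})
            continue
        report.extend(checker(path))
    return report
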