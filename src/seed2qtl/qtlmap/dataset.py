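"""Container and TSV I/O for a biparental RIL mapping dataset."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ..synthdata.rilsim import GeneticMap

__all__ = ["RilDataset"]

_CODE_MAP = {"A": 1.0, "B": -1.0, "NA": np.nan, "2": 1.0, "0": -1.0, "-1": np.nan}


@dataclass
class RilDataset:
    """Genetic map, +/-1-coded genotype matrix and phenotype table.

    Genotypes: lines x markers, +1 for the first-parent (Opata-type) allele,
    -1 for the second-parent (Synthetic-type) allele, NaN missing.  RILs are
    homozygous, so two codes suffice.
    """

    genetic_map: GeneticMap
    genotypes: pd.DataFrame
    phenotypes: pd.DataFrame

    def validate(self) -> None:
        markers = self.genetic_map.marker_names()
        if list(self.genotypes.columns) != markers:
            missing = set(markers) - set(self.genotypes.columns)
            if missing:
                raise ValueError(f"genotype matrix lacks mapped markers, e.g. {sorted(missing)[:3]}")
            self.genotypes = self.genotypes[markers]
        vals = self.genotypes.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 1.0) | (vals == -1.0)
        if not ok.all():
            bad = np.unique(vals[~ok])
            raise ValueError(f"genotype codes must be +/-1 or missing, found {bad[:5]}")
        if not self.genotypes.index.equals(self.phenotypes.index):
            common = self.genotypes.index.intersection(self.phenotypes.index)
            if len(common) < 2:
                raise ValueError("genotype and phenotype tables share <2 lines")
            self.genotypes = self.genotypes.loc[common]
            self.phenotypes = self.phenotypes.loc[common]

    @property
    def traits(self) -> list[str]:
        return list(self.phenotypes.columns)

    @property
    def n_lines(self) -> int:
        return len(self.genotypes)

    @classmethod
    def from_tsv(cls, map_path, geno_path, pheno_path) -> "RilDataset":
        gm = GeneticMap.from_frame(pd.read_csv(map_path, sep="\t"))
        geno = pd.read_csv(geno_path, sep="\t", index_col=0, dtype=str)
        geno = geno.apply(lambda col: col.map(lambda v: _CODE_MAP.get(str(v).strip(), np.nan)))
        pheno = pd.read_csv(pheno_path, sep="\t", index_col=0)
        ds = cls(genetic_map=gm, genotypes=geno, phenotypes=pheno)
        ds.validate()
        return ds

    def to_tsv(self, map_path, geno_path, pheno_path) -> None:
        for p in (map_path, geno_path, pheno_path):
            Path(p).parent.mkdir(parents=True, exist_ok=True)
        self.genetic_map.to_frame().to_csv(map_path, sep="\t", index=False)
        coded = self.genotypes.map(
            lambda v: "NA" if pd.isna(v) else ("A" if v > 0 else "B")
        )
        coded.to_csv(geno_path, sep="\t")
        self.phenotypes.to_csv(pheno_path, sep="\t")
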