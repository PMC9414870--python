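"""Run configuration: every analysis threshold is a named key with the
method's standard default, so any deviation is explicit in the config file
and echoed to the run log."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # analysis thresholds
    lod_significant: float = 2.0
    lod_highly_significant: float = 3.0
    epistasis_lod_min: float = 5.0
    epistasis_pve_min: float = 5.0       # percent
    additive_step_cm: float = 1.0
    epistasis_step_cm: float = 5.0
    tpm_min: float = 1.0
    outlier_sd_multiplier: float = 3.0
    n_dominant_clusters: int = 3
    min_seed_area_mm2: float = 2.0
    locus_tolerance_cm: float = 0.0
    # synthetic study conditions
    n_lines: int = 114
    n_chromosomes: int = 21
    marker_spacing_cm: float = 5.0
    chromosome_length_cm: float = 120.0
    residual_sd: float = 1.0
    seeds_per_image: tuple[int, int] = (15, 5)
    seed: int = 0
    # stage toggles
    run_imaging: bool = True
    run_epistasis: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> tuple["RunConfig", list[str]]:
        """Load a config; returns (config, list of non-default overrides)."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seeds_per_image" in data:
            data["seeds_per_image"] = tuple(data["seeds_per_image"])
        cfg = cls(**data)
        defaults = cls()
        overrides = [
            f"{f.name}: {getattr(cfg, f.name)!r} (default {getattr(defaults, f.name)!r})"
            for f in fields(cls)
            if getattr(cfg, f.name) != getattr(defaults, f.name)
        ]
        return cfg, overrides

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["seeds_per_image"] = list(d["seeds_per_image"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
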