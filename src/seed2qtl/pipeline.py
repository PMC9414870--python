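"""End-to-end orchestration of the five stages on synthetic data.

``run_pipeline`` renders seed images, phenotypes them, simulates a RIL
population with planted additive and epistatic QTLs, scans every simulated
trait, clusters traits by QTL overlap, builds prioritization fixtures around
the detected highly significant QTLs, and runs the candidate-gene cascade.
All outputs land in one run directory with a checksum manifest and a config
snapshot, so a rerun with the same seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .phenotyping import (
    apply_correction,
    detect_card_and_calibrate,
    phenotype_genotype,
    phenotype_image,
    segment_seeds,
)
from .prioritize import load_gene_annotation, prioritize_candidates, trait_class
from .qtlmap import RilDataset, epistasis_to_frame, results_to_frame, scan_all_traits
from .qtlmap.scan import epistasis_scan
from .similarity import build_locus_sets, cluster_traits, ochiai_matrix, to_newick
from .synthdata import (
    QtlPlan,
    RilSimSpec,
    default_map,
    make_prior_fixture,
    pve_to_effect,
    random_scene,
    render_seed_image,
    simulate_phenotypes,
    simulate_ril_genotypes,
)

__all__ = ["run_pipeline", "demo_sim_spec"]

# planted demo architecture over (chromosome index, position as fraction of
# map length, pve): shared loci across traits so the similarity stage has
# structure to find, plus one epistatic pair.
DEMO_TRAITS = [
    ("sA", [(0, 0.4, 0.25), (1, 0.3, 0.15)], []),
    ("sL", [(0, 0.4, 0.20)], []),
    ("RGB_mR", [(1, 0.8, 0.25)], []),
    ("Lab_mL", [(1, 0.8, 0.20), (2, 0.5, 0.15)], []),
    ("HSV_mS", [(2, 0.5, 0.20)], [((3, 0.3), (4, 0.7), 0.12)]),
]


def demo_sim_spec(cfg: RunConfig, trait_plan=None):
    """RIL simulation specs for the bundled planted-QTL demo."""
    gm = default_map(cfg.n_chromosomes, cfg.marker_spacing_cm, cfg.chromosome_length_cm)
    chroms = gm.chromosomes

    def locus(idx, frac):
        chrom = chroms[idx % len(chroms)]
        pos = gm.positions[chrom]
        return chrom, float(pos[0] + frac * (pos[-1] - pos[0]))

    specs = {}
    for i, (trait, qtls, epis) in enumerate(trait_plan or DEMO_TRAITS):
        specs[trait] = RilSimSpec(
            genetic_map=gm,
            n_lines=cfg.n_lines,
            qtl_spec=[(*locus(c, f), pve_to_effect(v, cfg.residual_sd)) for c, f, v in qtls],
            epi_spec=[(locus(ca, fa), locus(cb, fb), pve_to_effect(v, cfg.residual_sd))
                      for (ca, fa), (cb, fb), v in epis],
            residual_sd=cfg.residual_sd,
            seed=cfg.seed + 7919 * (i + 1),
        )
    return gm, specs


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig, outdir: str | Path, log=print) -> dict:
    """Run all stages; returns the manifest dict (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_lines: list[str] = []

    def say(msg: str):
        log_lines.append(msg)
        if log:
            log(msg)

    def write_tsv(df: pd.DataFrame, name: str, **kw):
        p = outdir / name
        df.to_csv(p, sep="\t", **kw)
        written.append(p)
        return p

    # stage 1+2: render two images of one genotype and phenotype them
    if cfg.run_imaging:
        say("[imaging] rendering and phenotyping the demo genotype")
        tables = []
        for i, n_seeds in enumerate(cfg.seeds_per_image):
            scene = random_scene(n_seeds, seed=cfg.seed + i, color_jitter=6.0)
            img, _, _ = render_seed_image(scene)
            cal = detect_card_and_calibrate(img)
            corrected = apply_correction(img, cal)
            contours = segment_seeds(corrected, cal, min_area_mm2=cfg.min_seed_area_mm2)
            tables.append(phenotype_image(corrected, contours, cal, image_id=f"img{i + 1}"))
        gvec, per_seed = phenotype_genotype(tables)
        write_tsv(per_seed, "traits_per_seed.tsv", index=False)
        write_tsv(gvec.to_frame("demo_genotype").T.rename_axis("genotype"), "traits_genotype.tsv")
        say(f"[imaging] {len(per_seed)} seeds phenotyped across {len(tables)} images")

    # stage 3: simulate the RIL study and scan
    say(f"[scan] simulating {cfg.n_lines} lines on {cfg.n_chromosomes} chromosomes")
    gm, specs = demo_sim_spec(cfg)
    geno = simulate_ril_genotypes(
        RilSimSpec(genetic_map=gm, n_lines=cfg.n_lines, seed=cfg.seed)
    )
    pheno_cols, truth_tabs = [], []
    for trait, spec in specs.items():
        y, truth = simulate_phenotypes(geno, spec, trait)
        pheno_cols.append(y)
        truth_tabs.append(truth)
    pheno = pd.concat(pheno_cols, axis=1)
    ds = RilDataset(genetic_map=gm, genotypes=geno, phenotypes=pheno)
    ds.validate()
    ds.to_tsv(outdir / "map.tsv", outdir / "genotypes.tsv", outdir / "phenotypes.tsv")
    written += [outdir / "map.tsv", outdir / "genotypes.tsv", outdir / "phenotypes.tsv"]
    write_tsv(pd.concat(truth_tabs, ignore_index=True), "planted_truth.tsv", index=False)

    profile, results = scan_all_traits(
        ds, step=cfg.additive_step_cm, lod_min=cfg.lod_significant
    )
    qtl_df = results_to_frame(results)
    write_tsv(qtl_df, "qtl_additive.tsv", index=False)
    say(f"[scan] {len(qtl_df)} additive QTLs detected")
    if cfg.run_epistasis:
        pairs = []
        for trait in ds.traits:
            pairs.extend(
                epistasis_scan(
                    ds, trait, step=cfg.epistasis_step_cm,
                    lod_min=cfg.epistasis_lod_min, pve_min=cfg.epistasis_pve_min,
                )
            )
        epi_df = epistasis_to_frame(pairs)
        write_tsv(epi_df, "qtl_epistatic.tsv", index=False)
        say(f"[scan] {len(epi_df)} epistatic pairs reported")

    # stage 4: trait similarity
    locus_sets = build_locus_sets(qtl_df, tolerance_cm=cfg.locus_tolerance_cm)
    sim = ochiai_matrix(locus_sets, traits=ds.traits)
    write_tsv(sim, "ochiai_matrix.tsv")
    linkage, labels, order = cluster_traits(sim)
    (outdir / "trait_tree.nwk").write_text(to_newick(linkage, labels) + "\n")
    written.append(outdir / "trait_tree.nwk")
    say(f"[similarity] {len(labels)} traits clustered")

    # stage 5: prioritization on fixtures built around the detected QTLs
    hs = qtl_df[qtl_df["LOD"] > cfg.lod_highly_significant]
    plans = [
        QtlPlan(
            name=r.qtl, trait=r.trait, chrom=r.chrom, peak_cm=r.peak_cM,
            trait_class=trait_class(r.trait), n_planted=1,
        )
        for r in hs.itertuples()
    ]
    n_candidates = 0
    if plans:
        fx = make_prior_fixture(plans, seed=cfg.seed)
        fx_paths = fx.write(outdir / "fixture")
        written += list(fx_paths.values())
        ann = load_gene_annotation(fx_paths["annotation"])
        cands, skipped = prioritize_candidates(
            fx.qtl_flanks, fx.marker_coords, ann, fx.expression, fx.gene2ko,
            set(fx.target_ko_size["ko"]), set(fx.target_ko_color["ko"]),
            lod_min=cfg.lod_highly_significant, tpm_min=cfg.tpm_min,
        )
        write_tsv(cands, "candidates.tsv", index=False)
        write_tsv(skipped, "skipped_qtls.tsv", index=False)
        n_candidates = len(cands)
    say(f"[prioritize] {n_candidates} candidate gene rows")

    cfg.to_yaml(outdir / "config_snapshot.yaml")
    written.append(outdir / "config_snapshot.yaml")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    manifest = {
        "seed": cfg.seed,
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(written))},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
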