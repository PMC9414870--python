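import numpy as np
import pytest

from seed2qtl.phenotyping import (
    apply_correction,
    detect_card_and_calibrate,
    segment_seeds,
)
from seed2qtl.qtlmap import RilDataset
from seed2qtl.synthdata import (
    RilSimSpec,
    default_map,
    pve_to_effect,
    random_scene,
    render_seed_image,
    simulate_phenotypes,
    simulate_ril_genotypes,
)


@pytest.fixture(scope="session")
def scene15():
    """A rendered 15-seed scene with ground truth (no cast, no noise)."""
    spec = random_scene(15, seed=1)
    img, labels, truth = render_seed_image(spec)
    return spec, img, labels, truth


@pytest.fixture(scope="session")
def calibrated15(scene15):
    """The 15-seed scene after calibration and segmentation."""
    spec, img, labels, truth = scene15
    cal = detect_card_and_calibrate(img)
    corrected = apply_correction(img, cal)
    contours = segment_seeds(corrected, cal)
    return spec, corrected, cal, contours, truth


def make_planted_dataset(
    n_lines=200, pve=0.20, chrom="1A", pos_cm=42.0, seed=0,
    n_chromosomes=3, spacing=5.0, length=120.0, trait="t", missing_rate=0.0,
):
    gm = default_map(n_chromosomes, spacing, length)
    eff = pve_to_effect(pve)
    spec = RilSimSpec(
        genetic_map=gm, n_lines=n_lines,
        qtl_spec=[(chrom, pos_cm, eff)] if pve > 0 else [],
        missing_rate=missing_rate, seed=seed,
    )
    geno = simulate_ril_genotypes(spec)
    y, truth = simulate_phenotypes(geno, spec, trait)
    ds = RilDataset(genetic_map=gm, genotypes=geno, phenotypes=y.to_frame())
    ds.validate()
    return ds, eff


@pytest.fixture(scope="session")
def planted_dataset():
    """200 RILs, one additive QTL at 1A:42 cM with 20% planted PVE."""
    ds, eff = make_planted_dataset(seed=5)
    return ds, eff


def disk_mask(radius_px: int, pad: int = 8) -> np.ndarray:
    n = 2 * (radius_px + pad) + 1
    yy, xx = np.mgrid[0:n, 0:n]
    c = radius_px + pad
    return ((xx - c) ** 2 + (yy - c) ** 2) <= radius_px**2
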