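"""Calibration, segmentation and the 55 descriptors against renderer ground truth."""

import numpy as np
import pytest

from seed2qtl.colorspaces import COLOR_SPACES, CHANNELS, rgb8_to_space
from seed2qtl.phenotyping import (
    CardNotFoundError,
    TRAIT_NAMES,
    apply_correction,
    contour_from_mask,
    detect_card_and_calibrate,
    measure_color,
    measure_shape,
    measure_size,
    phenotype_genotype,
    phenotype_image,
    segment_seeds,
    identity_calibration,
)
from seed2qtl.synthdata import SceneSpec, SeedGeom, random_scene, render_seed_image
from conftest import disk_mask


class TestCalibration:
    def test_identity_cast_recovers_identity(self, calibrated15):
        _, _, cal, _, _ = calibrated15
        assert np.allclose(cal.matrix, np.eye(3), atol=0.01)
        assert np.all(np.abs(cal.offset) < 1 / 255)

    def test_planted_linear_cast_inverted(self):
        m = np.array([[0.85, 0.05, 0.0], [0.02, 1.10, 0.03], [0.0, 0.04, 0.80]])
        spec = random_scene(5, seed=4, cast_matrix=m)
        img, _, _ = render_seed_image(spec)
        cal = detect_card_and_calibrate(img)
        # fitted correction approximately inverts the planted cast
        assert np.allclose(cal.matrix @ m, np.eye(3), atol=0.02)
        corrected_patches = apply_correction(
            img[cal.card_bbox[0]:cal.card_bbox[2], cal.card_bbox[1]:cal.card_bbox[3]], cal
        )
        assert cal.residual < 2.0  # 8-bit units

    def test_scale_from_card_width(self):
        spec = random_scene(3, seed=5, scale_mm_per_px=0.1)
        img, _, _ = render_seed_image(spec)
        cal = detect_card_and_calibrate(img)
        assert cal.scale_mm_per_px == pytest.approx(0.1, rel=0.01)

    def test_card_not_found_on_blank_image(self):
        blank = np.full((400, 600, 3), 250, dtype=np.uint8)
        with pytest.raises(CardNotFoundError):
            detect_card_and_calibrate(blank)


class TestSegmentation:
    def test_blank_scene_yields_zero_contours(self):
        img, _, _ = render_seed_image(SceneSpec(seeds=[]))
        cal = detect_card_and_calibrate(img)
        assert segment_seeds(apply_correction(img, cal), cal) == []

    def test_all_seeds_found_with_high_iou(self, scene15, calibrated15):
        _, _, labels, _ = scene15
        _, _, _, contours, _ = calibrated15
        assert len(contours) == 15
        for ct in contours:
            r0, c0, r1, c1 = ct.bbox
            region = labels[r0:r1, c0:c1]
            ids, counts = np.unique(region[ct.mask], return_counts=True)
            truth_id = ids[np.argmax(counts)]
            assert truth_id > 0
            truth_mask = labels == truth_id
            inter = (ct.mask & truth_mask[r0:r1, c0:c1]).sum()
            union = ct.mask.sum() + truth_mask.sum() - inter
            assert inter / union > 0.95

    def test_at_most_n_seeds_detected(self):
        spec = random_scene(20, seed=6, width_mm=220.0, height_mm=160.0)
        img, _, _ = render_seed_image(spec)
        cal = detect_card_and_calibrate(img)
        contours = segment_seeds(apply_correction(img, cal), cal)
        assert len(contours) <= 20


class TestSize:
    def test_circle_dimensions(self):
        cal = identity_calibration(0.02)  # radius 2 mm -> 100 px
        ct = contour_from_mask(disk_mask(100))
        size = measure_size(ct, cal)
        assert size["sL"] == pytest.approx(4.0, abs=0.02 * 2)
        assert size["sW"] == pytest.approx(4.0, abs=0.02 * 2)
        assert size["sA"] == pytest.approx(np.pi * 4.0, rel=0.02)

    @pytest.mark.parametrize("angle", [0.0, 30.0, 77.0])
    def test_rendered_ellipse_closed_form(self, angle):
        seed = SeedGeom(center_mm=(140.0, 100.0), a_mm=3.5, b_mm=1.6, angle_deg=angle)
        spec = SceneSpec(seeds=[seed], scale_mm_per_px=0.05)
        img, _, _ = render_seed_image(spec)
        cal = detect_card_and_calibrate(img)
        (ct,) = segment_seeds(apply_correction(img, cal), cal)
        size = measure_size(ct, cal)
        assert size["sL"] == pytest.approx(7.0, abs=0.1)
        assert size["sW"] == pytest.approx(3.2, abs=0.1)
        assert size["sA"] == pytest.approx(np.pi * 3.5 * 1.6, rel=0.02)

    def test_resolution_invariance(self):
        vals = {}
        for scale in (0.15, 0.075):
            seed = SeedGeom(center_mm=(140.0, 100.0), a_mm=3.5, b_mm=1.6, angle_deg=20.0)
            img, _, _ = render_seed_image(SceneSpec(seeds=[seed], scale_mm_per_px=scale))
            cal = detect_card_and_calibrate(img)
            (ct,) = segment_seeds(apply_correction(img, cal), cal)
            vals[scale] = measure_size(ct, cal)
        for k in ("sL", "sW", "sA"):
            assert vals[0.15][k] == pytest.approx(vals[0.075][k], rel=0.03)


class TestShape:
    def test_circle_indices_near_unity(self):
        ct = contour_from_mask(disk_mask(120))
        sh = measure_shape(ct)
        assert 0.97 <= sh["sCi"] <= 1.03
        assert 0.97 <= sh["sRo"] <= 1.03
        assert 0.97 <= sh["sSo"] <= 1.03
        assert 1.0 <= sh["sRg"] <= 1.05

    def test_ellipse_roundness_is_axis_ratio(self):
        # a = 2b: roundness 4A/(pi L^2) = b/a = 0.5, strictly below 1
        n = 512
        yy, xx = np.mgrid[0:n, 0:n]
        mask = (((xx - 256) / 160) ** 2 + ((yy - 256) / 80) ** 2) <= 1
        sh = measure_shape(contour_from_mask(mask))
        assert sh["sRo"] == pytest.approx(0.5, abs=0.02)
        assert sh["sRo"] < 1.0

    def test_convex_shape_bounds(self):
        mask = disk_mask(80)
        sh = measure_shape(contour_from_mask(mask))
        assert sh["sSo"] == pytest.approx(1.0, abs=0.01)
        assert sh["sRg"] == pytest.approx(1.0, abs=0.02)

    def test_rough_contour_raises_rugosity(self):
        seed_smooth = SeedGeom(center_mm=(140.0, 100.0), a_mm=4.0, b_mm=2.5)
        seed_rough = SeedGeom(center_mm=(140.0, 100.0), a_mm=4.0, b_mm=2.5, roughness=0.12)
        vals = {}
        for key, s in (("smooth", seed_smooth), ("rough", seed_rough)):
            img, _, _ = render_seed_image(SceneSpec(seeds=[s], scale_mm_per_px=0.05))
            cal = detect_card_and_calibrate(img)
            (ct,) = segment_seeds(apply_correction(img, cal), cal)
            vals[key] = measure_shape(ct)
        assert vals["rough"]["sRg"] > vals["smooth"]["sRg"]
        assert vals["rough"]["sRg"] > 1.02
        assert vals["rough"]["sSo"] < vals["smooth"]["sSo"]

    def test_rotation_invariance(self):
        base = {}
        for angle in (0.0, 37.0):
            seed = SeedGeom(center_mm=(140.0, 100.0), a_mm=4.0, b_mm=2.0, angle_deg=angle)
            img, _, _ = render_seed_image(SceneSpec(seeds=[seed], scale_mm_per_px=0.05))
            cal = detect_card_and_calibrate(img)
            (ct,) = segment_seeds(apply_correction(img, cal), cal)
            base[angle] = measure_shape(ct)
        for k in ("sCi", "sRo", "sRg", "sSo"):
            assert base[0.0][k] == pytest.approx(base[37.0][k], rel=0.02)

    def test_invariant_bounds_on_random_seeds(self, calibrated15):
        _, _, _, contours, _ = calibrated15
        for ct in contours:
            sh = measure_shape(ct)
            assert sh["sSo"] <= 1.0 + 1e-9
            assert sh["sRg"] >= 1.0 - 1e-9


class TestColor:
    def _uniform_seed(self, color=(139, 101, 57)):
        seed = SeedGeom(center_mm=(140.0, 100.0), a_mm=4.0, b_mm=2.5, color=color)
        img, _, _ = render_seed_image(SceneSpec(seeds=[seed]))
        cal = detect_card_and_calibrate(img)
        corrected = apply_correction(img, cal)
        (ct,) = segment_seeds(corrected, cal)
        return corrected, ct, cal

    def test_uniform_seed_reproduces_base_color_in_all_spaces(self):
        base = (139, 101, 57)
        corrected, ct, cal = self._uniform_seed(base)
        colors = measure_color(corrected, ct, cal)
        for space in COLOR_SPACES:
            expected = rgb8_to_space(np.array([base], dtype=float), space)[0]
            for j, ch in enumerate(CHANNELS[space]):
                assert colors[f"{space}_m{ch}"] == pytest.approx(expected[j], abs=1e-6)
                for i in (1, 2, 3):
                    assert colors[f"{space}_dC{ch}_{i}"] == pytest.approx(expected[j], abs=1e-6)

    def test_outlier_exclusion_beats_naive_mean(self):
        rng = np.random.default_rng(9)
        mask = np.ones((90, 90), dtype=bool)
        ct = contour_from_mask(mask)
        base = np.array([140.0, 100.0, 60.0])
        img = np.tile(base, (90, 90, 1)) + rng.normal(0, 2.0, (90, 90, 3))
        impulse = rng.random((90, 90)) < 0.02
        img[impulse] += 40.0
        img = np.clip(img, 0, 255)
        colors = measure_color(img, ct, erode_px=0)
        naive = img.reshape(-1, 3).mean(axis=0)
        for j, ch in enumerate(("R", "G", "B")):
            assert abs(colors[f"RGB_m{ch}"] - base[j]) < 0.5
            assert abs(naive[j] - base[j]) > 0.5

    def test_two_color_seed_dominant_clusters(self):
        mask = np.ones((100, 100), dtype=bool)
        ct = contour_from_mask(mask)
        img = np.empty((100, 100, 3))
        img[:70] = (200.0, 50.0, 50.0)   # 70% majority
        img[70:] = (50.0, 200.0, 50.0)   # 30% minority
        colors = measure_color(img, ct, erode_px=0)
        assert colors["RGB_dCR_1"] == pytest.approx(200.0, abs=1.0)
        assert colors["RGB_dCG_2"] == pytest.approx(200.0, abs=1.0)

    def test_color_invariant_to_planted_cast_after_calibration(self):
        base = (150, 96, 60)
        _, ct0, _ = self._uniform_seed(base)
        ref, ct, cal = self._uniform_seed(base)
        ref_colors = measure_color(ref, ct, cal)
        m = np.array([[0.9, 0.05, 0.0], [0.02, 1.05, 0.03], [0.0, 0.04, 0.85]])
        seed = SeedGeom(center_mm=(140.0, 100.0), a_mm=4.0, b_mm=2.5, color=base)
        img, _, _ = render_seed_image(SceneSpec(seeds=[seed], cast_matrix=m))
        cal2 = detect_card_and_calibrate(img)
        corrected = apply_correction(img, cal2)
        (ct2,) = segment_seeds(corrected, cal2)
        cast_colors = measure_color(corrected, ct2, cal2)
        for ch in ("R", "G", "B"):
            assert abs(cast_colors[f"RGB_m{ch}"] - ref_colors[f"RGB_m{ch}"]) <= 2.0


class TestTraitVector:
    def test_exactly_55_descriptors(self, calibrated15):
        _, corrected, cal, contours, _ = calibrated15
        table = phenotype_image(corrected, contours, cal)
        assert list(table.columns[2:]) == TRAIT_NAMES
        assert len(TRAIT_NAMES) == 55

    def test_genotype_pooling_is_unweighted_mean(self, calibrated15):
        _, corrected, cal, contours, _ = calibrated15
        t1 = phenotype_image(corrected, contours[:10], cal, image_id="a")
        t2 = phenotype_image(corrected, contours[10:], cal, image_id="b")
        gvec, pooled = phenotype_genotype([t1, t2])
        assert len(pooled) == 15
        assert np.allclose(gvec["sL"], pooled["sL"].mean())
        gvec_perm, _ = phenotype_genotype([t2, t1])
        assert np.allclose(gvec.to_numpy(), gvec_perm.to_numpy())

    def test_mean_of_two_seed_lengths(self, calibrated15):
        _, corrected, cal, contours, _ = calibrated15
        t = phenotype_image(corrected, contours[:2], cal)
        gvec, _ = phenotype_genotype([t])
        assert gvec["sL"] == pytest.approx((t["sL"][0] + t["sL"][1]) / 2)
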