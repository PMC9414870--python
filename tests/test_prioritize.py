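"""Filter-cascade semantics and the brute-force prioritization oracle."""

import numpy as np
import pandas as pd
import pytest

from seed2qtl.prioritize import (
    IntervalError,
    PhysicalInterval,
    filter_by_expression,
    genes_in_interval,
    load_gene_annotation,
    match_orthogroups,
    prioritize_candidates,
    qtl_to_interval,
    trait_class,
)
from seed2qtl.synthdata import QtlPlan, make_prior_fixture


@pytest.fixture(scope="module")
def fixture():
    plans = [
        QtlPlan(name="Q.sA-3A", trait="sA", chrom="3A", peak_cm=50.0,
                trait_class="size_shape", n_planted=2),
        QtlPlan(name="Q.RGB_mR-3B", trait="RGB_mR", chrom="3B", peak_cm=120.0,
                trait_class="color", n_planted=3),
        QtlPlan(name="Q.Lab_mb-5D", trait="Lab_mb", chrom="5D", peak_cm=30.0,
                trait_class="color", n_planted=1),
        QtlPlan(name="Q.sW-5A", trait="sW", chrom="5A", peak_cm=30.0,
                trait_class="size_shape", wrong_chromosome_marker=True),
    ]
    fx = make_prior_fixture(plans, seed=11)
    ann = load_gene_annotation(fx.annotation_gff3, from_string=True)
    return fx, ann


def brute_force_candidates(fx, ann, tpm_min=1.0):
    """Independent triple loop gene x QTL x filter."""
    coords = fx.marker_coords.set_index("marker")
    seed_tpm = (
        fx.expression[fx.expression["tissue"] == "seed"].groupby("gene")["tpm"].max()
    )
    target = {
        "size_shape": set(fx.target_ko_size["ko"]),
        "color": set(fx.target_ko_color["ko"]),
    }
    rows = []
    for _, q in fx.qtl_flanks.iterrows():
        lm, rm = coords.loc[q["left_marker"]], coords.loc[q["right_marker"]]
        if str(lm["chrom"]) != q["chrom"] or str(rm["chrom"]) != q["chrom"]:
            continue
        lo = min(lm["start"], rm["start"])
        hi = max(lm["end"], rm["end"])
        for _, g in ann.iterrows():
            if g["chrom"] != q["chrom"] or g["end"] < lo or g["start"] > hi:
                continue
            if g["confidence"] != "high":
                continue
            if q["trait_class"] == "color" and seed_tpm.get(g["gene"], 0.0) < tpm_min:
                continue
            for _, k in fx.gene2ko[fx.gene2ko["gene"] == g["gene"]].iterrows():
                if k["ko"] in target[q["trait_class"]]:
                    rows.append((q["qtl"], g["gene"], k["ko"]))
    return sorted(set(rows))


class TestInterval:
    def test_interval_spans_flank_extremes(self):
        coords = pd.DataFrame(
            [("L", "3D", 1_000_000, 1_200_000), ("R", "3D", 2_500_000, 2_600_000)],
            columns=["marker", "chrom", "start", "end"],
        )
        row = {"qtl": "Q.x-3D", "chrom": "3D", "left_marker": "L", "right_marker": "R"}
        iv = qtl_to_interval(row, coords)
        assert (iv.chrom, iv.start, iv.end) == ("3D", 1_000_000, 2_600_000)

    def test_wrong_chromosome_marker_raises(self):
        coords = pd.DataFrame(
            [("L", "5A", 10, 20), ("R", "3D", 30, 40)],
            columns=["marker", "chrom", "start", "end"],
        )
        row = {"qtl": "Q.x-3D", "chrom": "3D", "left_marker": "L", "right_marker": "R"}
        with pytest.raises(IntervalError, match="5A"):
            qtl_to_interval(row, coords)

    def test_missing_marker_raises(self):
        coords = pd.DataFrame([("L", "3D", 10, 20)], columns=["marker", "chrom", "start", "end"])
        row = {"qtl": "Q.x-3D", "chrom": "3D", "left_marker": "L", "right_marker": "Z"}
        with pytest.raises(IntervalError, match="no physical coordinates"):
            qtl_to_interval(row, coords)

    def test_sub_threshold_lod_excluded_from_cascade(self, fixture):
        fx, ann = fixture
        q = fx.qtl_flanks.copy()
        q["LOD"] = 2.8
        cands, _ = prioritize_candidates(
            q, fx.marker_coords, ann, fx.expression, fx.gene2ko,
            set(fx.target_ko_size["ko"]), set(fx.target_ko_color["ko"]),
        )
        assert cands.empty


class TestGeneFilters:
    def test_overlap_rules(self):
        ann = pd.DataFrame(
            [
                ("inside", "1A", 150, 160, "high"),
                ("edge", "1A", 90, 100, "high"),       # overlaps start by 1 bp
                ("outside", "1A", 10, 99, "high"),
                ("lowconf", "1A", 150, 160, "low"),
                ("other_chrom", "1B", 150, 160, "high"),
            ],
            columns=["gene", "chrom", "start", "end", "confidence"],
        )
        iv = PhysicalInterval(chrom="1A", start=100, end=200)
        assert genes_in_interval(ann, iv) == ["edge", "inside"]

    def test_expression_filter(self):
        expr = pd.DataFrame(
            [
                ("g1", "s1", "seed", 5.2),
                ("g2", "s1", "seed", 0.5),
                ("g2", "s2", "seed", 0.8),
                ("g3", "s1", "leaf", 50.0),
            ],
            columns=["gene", "sample", "tissue", "tpm"],
        )
        assert filter_by_expression(["g1", "g2", "g3"], expr) == ["g1"]

    def test_expression_bypassed_for_size_traits(self, fixture):
        fx, ann = fixture
        cands_default, _ = prioritize_candidates(
            fx.qtl_flanks, fx.marker_coords, ann, fx.expression, fx.gene2ko,
            set(fx.target_ko_size["ko"]), set(fx.target_ko_color["ko"]),
        )
        cands_all_filtered, _ = prioritize_candidates(
            fx.qtl_flanks, fx.marker_coords, ann, fx.expression, fx.gene2ko,
            set(fx.target_ko_size["ko"]), set(fx.target_ko_color["ko"]),
            expression_filter_classes=("color", "size_shape"),
        )
        # size/shape candidates are unaffected because planted genes are expressed,
        # and the bypass never *adds* color candidates
        assert set(cands_default[cands_default.trait_class == "color"]["gene"]) == set(
            cands_all_filtered[cands_all_filtered.trait_class == "color"]["gene"]
        )

    def test_gene_without_ko_is_silently_dropped(self):
        g2k = pd.DataFrame(
            [("g1", "K00001", "", "", "", "")],
            columns=["gene", "ko", "ko_description", "ec", "pathway", "pathway_description"],
        )
        hits = match_orthogroups(["g1", "g2"], g2k, {"K00001"})
        assert list(hits["gene"]) == ["g1"]

    def test_trait_class_mapping(self):
        assert trait_class("sA") == "size_shape"
        assert trait_class("sRg") == "size_shape"
        assert trait_class("RGB_dCR_1") == "color"
        assert trait_class("Lab_mL") == "color"


class TestCascade:
    def test_matches_brute_force_oracle_exactly(self, fixture):
        fx, ann = fixture
        cands, skipped = prioritize_candidates(
            fx.qtl_flanks, fx.marker_coords, ann, fx.expression, fx.gene2ko,
            set(fx.target_ko_size["ko"]), set(fx.target_ko_color["ko"]),
        )
        got = sorted(set(zip(cands["qtl"], cands["gene"], cands["ko"])))
        assert got == brute_force_candidates(fx, ann)
        assert list(skipped["qtl"]) == ["Q.sW-5A"]

    def test_planted_candidates_returned_exactly(self, fixture):
        fx, ann = fixture
        cands, _ = prioritize_candidates(
            fx.qtl_flanks, fx.marker_coords, ann, fx.expression, fx.gene2ko,
            set(fx.target_ko_size["ko"]), set(fx.target_ko_color["ko"]),
        )
        reachable = [
            g for q, genes in fx.planted_by_qtl.items() for g in genes
            if q != "Q.sW-5A"  # that QTL's interval is unmappable by construction
        ]
        assert sorted(set(cands["gene"])) == sorted(reachable)

    def test_monotone_in_tpm_threshold(self, fixture):
        fx, ann = fixture
        prev = None
        for tpm_min in (0.0, 1.0, 10.0, 1000.0):
            cands, _ = prioritize_candidates(
                fx.qtl_flanks, fx.marker_coords, ann, fx.expression, fx.gene2ko,
                set(fx.target_ko_size["ko"]), set(fx.target_ko_color["ko"]),
                tpm_min=tpm_min,
            )
            rows = set(zip(cands["qtl"], cands["gene"], cands["ko"]))
            if prev is not None:
                assert rows <= prev
            prev = rows

    def test_enlarging_interval_never_removes_candidates(self, fixture):
        fx, ann = fixture
        iv_small = PhysicalInterval(chrom="3A", start=46_000_000, end=54_000_000)
        iv_big = PhysicalInterval(chrom="3A", start=40_000_000, end=80_000_000)
        assert set(genes_in_interval(ann, iv_small)) <= set(genes_in_interval(ann, iv_big))

    def test_rerun_is_bit_identical(self, fixture):
        fx, ann = fixture
        args = (
            fx.qtl_flanks, fx.marker_coords, ann, fx.expression, fx.gene2ko,
            set(fx.target_ko_size["ko"]), set(fx.target_ko_color["ko"]),
        )
        c1, s1 = prioritize_candidates(*args)
        c2, s2 = prioritize_candidates(*args)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(s1, s2)
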