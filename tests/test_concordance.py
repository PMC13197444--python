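"""Lesion labeling, overlap matching and concordance/site adjudication."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import as_volume, random_blob_mask
from dualpet.concordance import (
    adjudicate_concordance,
    classify_site,
    flag_spleen,
    label_components,
    overlap_matrix,
    threshold_segment,
)
from dualpet.errors import DomainError, GridMismatchError
from oracles import adjudicate_by_loops, flood_fill_label, pair_overlaps, site_by_loops


class TestLabelComponents:
    def test_empty_mask(self):
        ls = label_components(as_volume(np.zeros((5, 5, 5), np.uint8)))
        assert len(ls) == 0

    def test_corner_touching_cubes_merge_under_26_connectivity(self):
        m = np.zeros((8, 8, 8), np.uint8)
        m[0:3, 0:3, 0:3] = 1
        m[3:6, 3:6, 3:6] = 1
        assert len(label_components(as_volume(m), connectivity=26)) == 1
        assert len(label_components(as_volume(m), connectivity=6)) == 2

    def test_volume_and_centroid(self):
        m = np.zeros((10, 10, 10), np.uint8)
        m[2:4, 2:4, 2:4] = 1  # 8 voxels
        ls = label_components(as_volume(m, spacing=(2.0, 2.0, 3.0)))
        les = ls.lesions[0]
        assert les.n_voxels == 8
        assert les.volume_ml == pytest.approx(8 * 2 * 2 * 3 / 1000.0)
        np.testing.assert_allclose(les.centroid_mm, [2.5 * 2, 2.5 * 2, 2.5 * 3])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_flood_fill_oracle(self, seed):
        r = np.random.default_rng(seed)
        m = (r.random((30, 30, 30)) > 0.82).astype(np.uint8)
        ours = label_components(as_volume(m)).labels.values
        oracle = flood_fill_label(m, 26)
        # same partition up to label permutation
        assert ours.max() == oracle.max()
        for l in range(1, oracle.max() + 1):
            vals = np.unique(ours[oracle == l])
            assert len(vals) == 1 and vals[0] > 0

    def test_grid_mismatch_rejected(self):
        m = as_volume(np.zeros((5, 5, 5), np.uint8))
        pet = as_volume(np.zeros((5, 5, 6)), units="SUV")
        with pytest.raises(GridMismatchError):
            label_components(m, pet)


class TestThresholdSegment:
    def test_threshold_extremes_and_blob_recovery(self):
        body = np.ones((10, 10, 10), np.uint8)
        pet = np.ones((10, 10, 10))
        pet[3:6, 3:6, 3:6] = 4.0
        petv, bodyv = as_volume(pet, units="SUV"), as_volume(body)
        assert threshold_segment(petv, 0.0, bodyv).values.sum() == 1000
        assert threshold_segment(petv, 99.0, bodyv).values.sum() == 0
        rec = threshold_segment(petv, 2.5, bodyv).values
        expect = np.zeros_like(body)
        expect[3:6, 3:6, 3:6] = 1
        np.testing.assert_array_equal(rec, expect)


class TestOverlapMatrix:
    def test_disjoint_and_identical(self):
        a = np.zeros((10, 10, 10), np.uint8)
        a[1:4, 1:4, 1:4] = 1
        b = np.zeros_like(a)
        b[6:9, 6:9, 6:9] = 1
        la = label_components(as_volume(a), tracer="FDG")
        lb = label_components(as_volume(b), tracer="CXCR4")
        assert len(overlap_matrix(la, lb)) == 0
        lb2 = label_components(as_volume(a), tracer="CXCR4")
        pairs = overlap_matrix(la, lb2)
        assert len(pairs) == 1
        assert pairs.iloc[0]["intersection_voxels"] == 27

    @pytest.mark.parametrize("seed", [3, 4])
    def test_counts_match_voxel_loop_oracle(self, seed):
        r = np.random.default_rng(seed)
        a = random_blob_mask(r, n_blobs=4)
        b = random_blob_mask(r, n_blobs=4)
        la = label_components(as_volume(a), tracer="FDG")
        lb = label_components(as_volume(b), tracer="CXCR4")
        pairs = overlap_matrix(la, lb)
        oracle = pair_overlaps(la.labels.values, lb.labels.values)
        got = {
            (row.label_a, row.label_b): row.intersection_voxels
            for row in pairs.itertuples()
        }
        assert got == oracle


def _pair_sets(seed, shape=(20, 20, 20)):
    r = np.random.default_rng(seed)
    a = random_blob_mask(r, shape)
    b = random_blob_mask(r, shape)
    la = label_components(as_volume(a), tracer="FDG")
    lb = label_components(as_volume(b), tracer="CXCR4")
    return la, lb


class TestAdjudication:
    def test_identical_lesions_fully_concordant(self):
        m = np.zeros((10, 10, 10), np.uint8)
        m[2:5, 2:5, 2:5] = 1
        la = label_components(as_volume(m), tracer="FDG")
        lb = label_components(as_volume(m), tracer="CXCR4")
        table = adjudicate_concordance(overlap_matrix(la, lb), la, lb)
        assert table.pairs.iloc[0]["overlap_fraction"] == 1.0
        assert all(v == "concordant" for v in table.category.values())
        assert table.counts() == {"concordant": 1, "FDG_only": 0, "CXCR4_only": 0}

    def test_exactly_ten_percent_is_not_concordant(self):
        # smaller lesion 10 voxels, exactly 1 shared voxel -> fraction 0.10
        a = np.zeros((20, 6, 6), np.uint8)
        a[0:10, 0, 0] = 1
        b = np.zeros_like(a)
        b[9:15, :, :] = 1  # large block sharing exactly voxel (9,0,0)
        la = label_components(as_volume(a), tracer="FDG")
        lb = label_components(as_volume(b), tracer="CXCR4")
        pairs = overlap_matrix(la, lb)
        assert pairs.iloc[0]["intersection_voxels"] == 1
        table = adjudicate_concordance(pairs, la, lb, threshold=0.10)
        assert table.pairs.iloc[0]["overlap_fraction"] == pytest.approx(0.10)
        assert table.category[("FDG", 1)] == "FDG_only"
        assert table.category[("CXCR4", 1)] == "CXCR4_only"
        # non-strict mode flips the call
        loose = adjudicate_concordance(pairs, la, lb, threshold=0.10, strict=False)
        assert loose.category[("FDG", 1)] == "concordant"

    def test_threshold_domain(self):
        la, lb = _pair_sets(0)
        pairs = overlap_matrix(la, lb)
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(DomainError):
                adjudicate_concordance(pairs, la, lb, threshold=bad)

    @pytest.mark.parametrize("seed", range(6))
    def test_categories_match_voxel_loop_oracle(self, seed):
        la, lb = _pair_sets(seed)
        table = adjudicate_concordance(overlap_matrix(la, lb), la, lb)
        cat_a, cat_b = adjudicate_by_loops(la.labels.values, lb.labels.values)
        for l, c in cat_a.items():
            want = "concordant" if c == "concordant" else "FDG_only"
            assert table.category[("FDG", l)] == want
        for l, c in cat_b.items():
            want = "concordant" if c == "concordant" else "CXCR4_only"
            assert table.category[("CXCR4", l)] == want

    def test_symmetry_under_tracer_swap(self):
        la, lb = _pair_sets(7)
        t1 = adjudicate_concordance(overlap_matrix(la, lb), la, lb)
        pairs_swapped = overlap_matrix(lb, la)
        t2 = adjudicate_concordance(pairs_swapped, lb, la)
        c1 = {k: v for k, v in t1.category.items()}
        c2 = {k: v for k, v in t2.category.items()}
        for (tracer, label), cat in c1.items():
            assert (c2[(tracer, label)] == "concordant") == (cat == "concordant")
        assert t1.counts()["concordant"] == t2.counts()["concordant"]

    def test_threshold_monotonicity(self):
        la, lb = _pair_sets(11)
        pairs = overlap_matrix(la, lb)
        counts = [
            adjudicate_concordance(pairs, la, lb, threshold=t).counts()["concordant"]
            for t in (0.05, 0.10, 0.20, 0.40, 0.80)
        ]
        assert counts == sorted(counts, reverse=True)

    @pytest.mark.parametrize("seed", range(4))
    def test_partition_identity(self, seed):
        la, lb = _pair_sets(seed + 20)
        table = adjudicate_concordance(overlap_matrix(la, lb), la, lb)
        c = table.counts()
        n_conc_lesions = sum(
            1 for v in table.category.values() if v == "concordant"
        )
        assert c["concordant"] <= n_conc_lesions
        assert (
            c["concordant"] + c["FDG_only"] + c["CXCR4_only"]
            == table.n_distinct_lesions
        )
        # every lesion categorized exactly once
        assert len(table.category) == len(la) + len(lb)


class TestSiteAndSpleen:
    def _lesion(self, mask):
        return label_components(as_volume(mask)).lesions[0]

    def test_fully_inside_bone_is_medullary(self):
        m = np.zeros((10, 10, 10), np.uint8)
        m[2:4, 2:4, 2:4] = 1
        bone = np.ones_like(m)
        assert classify_site(self._lesion(m), as_volume(bone)) == "medullary"

    def test_no_bone_overlap_is_extramedullary(self):
        m = np.zeros((10, 10, 10), np.uint8)
        m[2:4, 2:4, 2:4] = 1
        assert classify_site(self._lesion(m), as_volume(np.zeros_like(m))) == "extramedullary"

    def test_exactly_ten_percent_bone_is_medullary_inclusive(self):
        m = np.zeros((20, 5, 5), np.uint8)
        m[0:10, 0, 0] = 1  # 10 voxels
        bone = np.zeros_like(m)
        bone[0, 0, 0] = 1  # exactly 1/10
        assert classify_site(self._lesion(m), as_volume(bone), threshold=0.10) == "medullary"

    @pytest.mark.parametrize("seed", [5, 6])
    def test_site_matches_voxel_loop_oracle(self, seed):
        r = np.random.default_rng(seed)
        mask = random_blob_mask(r)
        bone = random_blob_mask(r, n_blobs=2, r_range=(4, 7))
        ls = label_components(as_volume(mask))
        oracle = site_by_loops(ls.labels.values, bone)
        for les in ls.lesions:
            assert classify_site(les, as_volume(bone)) == oracle[les.label]

    def test_spleen_flag_single_shared_voxel(self):
        m = np.zeros((10, 10, 10), np.uint8)
        m[2:5, 2:5, 2:5] = 1
        les = self._lesion(m)
        spleen = np.zeros_like(m)
        assert not flag_spleen(les, as_volume(spleen))
        spleen[4, 4, 4] = 1
        assert flag_spleen(les, as_volume(spleen))


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 10_000))
def test_lowering_threshold_never_loses_concordant_lesions(seed):
    la, lb = _pair_sets(seed)
    pairs = overlap_matrix(la, lb)
    lo = adjudicate_concordance(pairs, la, lb, threshold=0.05).counts()["concordant"]
    hi = adjudicate_concordance(pairs, la, lb, threshold=0.30).counts()["concordant"]
    assert lo >= hi
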