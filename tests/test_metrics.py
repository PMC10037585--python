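"""Accuracy metrics against brute-force set/distance oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

from tibiaseg.metrics import (
    CaseMetrics,
    compare_scenarios,
    hausdorff_mm,
    implied_ji,
    jaccard,
    summarize,
    volume_error,
    volume_intersection_ratio,
)
from tibiaseg.volume_io import BinaryMask, VolumeGeometry

from .conftest import make_mask, random_mask


# -- independent oracles -----------------------------------------------------


def brute_overlap(seg: BinaryMask, ref: BinaryMask):
    """Set-arithmetic oracle over explicit voxel coordinate sets."""
    s = {tuple(c) for c in np.argwhere(seg.labels)}
    r = {tuple(c) for c in np.argwhere(ref.labels)}
    inter = len(s & r)
    return {
        "ji": 100.0 * inter / len(s | r),
        "vi": 100.0 * inter / len(s) if s else None,
        "ve": 100.0 * (len(s) - len(r)) / len(r),
    }


def brute_hausdorff(seg: BinaryMask, ref: BinaryMask) -> float:
    """All-pairs nearest-neighbour oracle in physical coordinates."""
    sp = np.asarray(seg.geometry.spacing)
    s = np.argwhere(seg.labels) * sp
    r = np.argwhere(ref.labels) * sp
    d = np.sqrt(((s[:, None, :] - r[None, :, :]) ** 2).sum(-1))
    return max(d.min(axis=1).max(), d.min(axis=0).max())


# -- worked examples ---------------------------------------------------------


class TestOverlapExamples:
    def test_identity_and_disjoint(self, cube_geometry):
        a = make_mask(cube_geometry, [(0, 0, 0), (1, 1, 1)])
        b = make_mask(cube_geometry, [(2, 2, 2)])
        assert jaccard(a, a) == 100.0
        assert jaccard(a, b) == 0.0
        assert volume_intersection_ratio(a, a) == 100.0
        assert volume_error(a, a) == 0.0

    def test_partial_overlap_counts(self, cube_geometry):
        seg = make_mask(cube_geometry, [(0, 0, 0), (0, 0, 1)])
        ref = make_mask(cube_geometry, [(0, 0, 0), (0, 1, 0)])
        assert jaccard(seg, ref) == pytest.approx(100 / 3, abs=0.01)
        assert volume_intersection_ratio(seg, ref) == 50.0

    def test_containment_gives_full_intersection_ratio(self, cube_geometry):
        seg = make_mask(cube_geometry, [(1, 1, 1)])
        ref = make_mask(cube_geometry, [(1, 1, 1), (1, 1, 2), (0, 1, 1)])
        assert volume_intersection_ratio(seg, ref) == 100.0

    def test_volume_error_sign_convention(self):
        geom = VolumeGeometry(dims=(10, 10, 10), spacing=(1, 1, 1))
        labels = np.zeros(geom.dims, np.uint8)
        labels.ravel()[:114] = 1
        seg = BinaryMask(geom, labels)
        ref_labels = np.zeros(geom.dims, np.uint8)
        ref_labels.ravel()[:100] = 1
        ref = BinaryMask(geom, ref_labels)
        assert volume_error(seg, ref) == pytest.approx(14.0)  # over-segmentation
        empty = BinaryMask(geom, np.zeros(geom.dims, np.uint8))
        assert volume_error(empty, ref) == -100.0

    def test_empty_operands_raise(self, cube_geometry):
        full = make_mask(cube_geometry, [(0, 0, 0)])
        empty = make_mask(cube_geometry, [])
        with pytest.raises(ValueError):
            jaccard(full, empty)
        with pytest.raises(ValueError):
            volume_intersection_ratio(empty, full)
        with pytest.raises(ValueError):
            volume_error(full, empty)
        with pytest.raises(ValueError):
            hausdorff_mm(full, empty)

    def test_geometry_mismatch_raises(self, cube_geometry, small_geometry):
        a = make_mask(cube_geometry, [(0, 0, 0)])
        b = make_mask(small_geometry, [(0, 0, 0)])
        with pytest.raises(ValueError, match="mismatch"):
            jaccard(a, b)


class TestHausdorff:
    def test_identity_zero(self, cube_geometry):
        m = make_mask(cube_geometry, [(0, 0, 0), (2, 1, 0)])
        assert hausdorff_mm(m, m) == 0.0

    def test_single_voxel_offset_along_first_axis(self, cube_geometry):
        a = make_mask(cube_geometry, [(0, 0, 0)])
        b = make_mask(cube_geometry, [(1, 0, 0)])
        assert hausdorff_mm(a, b) == pytest.approx(0.09, abs=1e-9)

    def test_matches_brute_force_on_toy_masks(self, cube_geometry):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = random_mask(cube_geometry, rng, p=0.3)
            b = random_mask(cube_geometry, rng, p=0.3)
            if a.voxel_count == 0 or b.voxel_count == 0:
                continue
            assert hausdorff_mm(a, b) == pytest.approx(
                brute_hausdorff(a, b), rel=1e-9
            )


class TestBruteForceEquivalence:
    def test_all_metrics_match_oracles_on_3cube_sample(self, cube_geometry):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 30:
            a = random_mask(cube_geometry, rng, p=0.45)
            b = random_mask(cube_geometry, rng, p=0.45)
            if a.voxel_count == 0 or b.voxel_count == 0:
                continue
            oracle = brute_overlap(a, b)
            assert jaccard(a, b) == pytest.approx(oracle["ji"], rel=1e-12)
            assert volume_intersection_ratio(a, b) == pytest.approx(
                oracle["vi"], rel=1e-12
            )
            assert volume_error(a, b) == pytest.approx(oracle["ve"], rel=1e-12)
            assert hausdorff_mm(a, b) == pytest.approx(
                brute_hausdorff(a, b), rel=1e-9
            )
            checked += 1

    def test_jaccard_symmetric_others_not(self, cube_geometry):
        rng = np.random.default_rng(3)
        a = random_mask(cube_geometry, rng, p=0.5)
        b = random_mask(cube_geometry, rng, p=0.3)
        assert jaccard(a, b) == jaccard(b, a)
        assert volume_intersection_ratio(a, b) != volume_intersection_ratio(b, a)
        assert volume_error(a, b) != volume_error(b, a)

    def test_invariant_under_axis_permutation(self):
        rng = np.random.default_rng(9)
        geom = VolumeGeometry(dims=(4, 5, 6), spacing=(0.09, 0.075, 0.094))
        a = random_mask(geom, rng, p=0.4)
        b = random_mask(geom, rng, p=0.4)
        perm = (2, 0, 1)
        geom_p = VolumeGeometry(
            dims=tuple(geom.dims[i] for i in perm),
            spacing=tuple(geom.spacing[i] for i in perm),
        )
        ap = BinaryMask(geom_p, np.transpose(a.labels, perm))
        bp = BinaryMask(geom_p, np.transpose(b.labels, perm))
        assert jaccard(ap, bp) == jaccard(a, b)
        assert hausdorff_mm(ap, bp) == pytest.approx(hausdorff_mm(a, b), rel=1e-12)


class TestImpliedJi:
    def test_perfect_segmentation(self):
        assert implied_ji(100.0, 0.0) == 100.0

    def test_identity_holds_exactly_for_random_masks(self):
        rng = np.random.default_rng(21)
        geom = VolumeGeometry(dims=(16, 16, 16), spacing=(1, 1, 1))
        for _ in range(40):
            a = random_mask(geom, rng, p=rng.uniform(0.1, 0.6))
            b = random_mask(geom, rng, p=rng.uniform(0.1, 0.6))
            if a.voxel_count == 0 or b.voxel_count == 0:
                continue
            ji = jaccard(a, b)
            if ji == 0.0:
                continue
            assert implied_ji(
                volume_intersection_ratio(a, b), volume_error(a, b)
            ) == pytest.approx(ji, rel=1e-9)

    @pytest.mark.parametrize(
        "vi,ve,printed_aji",
        [(94.64, -1.44, 88.63), (90.21, 1.71, 83.45)],
    )
    def test_published_full_training_rows_are_self_consistent(
        self, vi, ve, printed_aji
    ):
        # identity applied to reported (AVI, AVE) reproduces the reported AJI
        assert implied_ji(vi, ve) == pytest.approx(printed_aji, abs=0.1)

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            implied_ji(0.0, 5.0)
        with pytest.raises(ValueError):
            implied_ji(50.0, -100.0)


class TestSummarize:
    def test_two_case_mean_and_sample_sd(self):
        cases = [
            CaseMetrics(ji=80, vi=90, ve=5, hd=0.2),
            CaseMetrics(ji=90, vi=92, ve=-5, hd=0.4),
        ]
        s = summarize(cases)
        assert s.aji == pytest.approx(85.0)
        assert s.aji_sd == pytest.approx(7.0710678, abs=1e-6)
        assert s.sd_defined

    def test_single_case_flags_undefined_sd(self):
        s = summarize([CaseMetrics(ji=80, vi=90, ve=5, hd=0.2)])
        assert s.aji == 80 and s.aji_sd == 0.0 and not s.sd_defined

    def test_constant_list_zero_sd(self):
        s = summarize([CaseMetrics(ji=80, vi=90, ve=5, hd=0.2)] * 3)
        assert s.aji_sd == 0.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestCompareScenarios:
    def test_identical_samples_not_significant(self):
        t, p, sig = compare_scenarios([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0 and not sig

    def test_constant_nonzero_difference_is_degenerate(self):
        t, p, sig = compare_scenarios([1.0, 2.0], [3.0, 4.0])
        assert np.isnan(t) and np.isnan(p) and not sig

    def test_p_value_matches_t_cdf_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.normal(80, 5, size=10)
        b = a + rng.normal(1.0, 2.0, size=10)
        t, p, _ = compare_scenarios(a, b)
        d = a - b
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_oracle = 2 * stats.t.sf(abs(t_oracle), len(d) - 1)
        assert t == pytest.approx(t_oracle, abs=1e-6)
        assert p == pytest.approx(p_oracle, abs=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_scenarios([1.0, 2.0], [1.0])
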