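"""Synthetic cohort generator: anatomy, determinism, census, perturbations."""

import numpy as np
import pytest
from scipy import ndimage

from tibiaseg.phantom import (
    AnnotatorModel,
    CohortSpec,
    MousePlan,
    PhantomSpec,
    RetestPerturbation,
    cohort_census,
    generate_retest_pair,
    generate_tibia_phantom,
    plan_cohort,
    simulate_annotator,
)
from tibiaseg.repeatability import PairedVolumes, wcv
from tibiaseg.volume_io import VolumeGeometry, mask_volume_mm3

_TINY = CohortSpec.tiny()
TINY_GEOM = _TINY.geometry
TINY_PERT = _TINY.perturbation


def tiny_spec(seed=0, **kw) -> PhantomSpec:
    """Phantom spec under the scaled cohort's study conditions."""
    from dataclasses import replace

    return replace(_TINY.phantom_template, seed=seed, **kw)


class TestTibiaPhantom:
    def test_reference_phantom_volume_in_study_range(self):
        # full-resolution check; the observed tibia range is 6.5-9.9 mm^3
        vol, mask = generate_tibia_phantom(PhantomSpec(seed=1))
        assert 6.5 <= mask_volume_mm3(mask) <= 9.9

    def test_mask_is_single_26_connected_component(self):
        _, mask = generate_tibia_phantom(tiny_spec(seed=2))
        _, n = ndimage.label(mask.labels, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_volume_targeting(self):
        for target in (6.5, 8.0, 9.9):
            _, mask = generate_tibia_phantom(tiny_spec(target_volume_mm3=target))
            assert mask_volume_mm3(mask) == pytest.approx(target, rel=0.06)

    def test_no_noise_limit_is_piecewise_constant(self):
        spec = tiny_spec(
            noise_sigma=0.0,
            marrow_heterogeneity=0.0,
            background_sd=0.0,
            cortical_attenuation=1.0,
        )
        vol, _ = generate_tibia_phantom(spec)
        assert len(np.unique(vol.intensities)) == 2  # background and marrow

    def test_dark_rim_between_marrow_and_background(self):
        spec = tiny_spec(noise_sigma=0.0, marrow_heterogeneity=0.0, background_sd=0.0)
        vol, mask = generate_tibia_phantom(spec)
        interior = ndimage.binary_erosion(
            mask.labels.astype(bool), iterations=spec.cortical_rim_voxels
        )
        rim = mask.labels.astype(bool) & ~interior
        assert vol.intensities[rim].mean() < vol.intensities[~mask.labels.astype(bool)].mean() * 2
        assert vol.intensities[rim].mean() < vol.intensities[interior].mean() * 0.5

    def test_deterministic_under_seed(self):
        a_vol, a_mask = generate_tibia_phantom(tiny_spec(seed=5))
        b_vol, b_mask = generate_tibia_phantom(tiny_spec(seed=5))
        np.testing.assert_array_equal(a_vol.intensities, b_vol.intensities)
        np.testing.assert_array_equal(a_mask.labels, b_mask.labels)

    def test_intensities_within_14bit_range(self):
        vol, _ = generate_tibia_phantom(tiny_spec(seed=3))
        assert vol.intensities.min() >= 0
        assert vol.intensities.max() <= 2**14 - 1

    def test_too_small_geometry_rejected(self):
        geom = VolumeGeometry(dims=(8, 8, 16), spacing=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            generate_tibia_phantom(PhantomSpec(geometry=geom, shaft_length_mm=17.0))


class TestRetestPair:
    def test_identity_perturbation_with_shared_noise(self):
        pert = RetestPerturbation(
            max_rotation_deg=0.0, max_translation_voxels=0.0, independent_noise=False
        )
        (v1, m1), (v2, m2) = generate_retest_pair(tiny_spec(seed=4), pert)
        np.testing.assert_array_equal(v1.intensities, v2.intensities)
        np.testing.assert_array_equal(m1.labels, m2.labels)

    def test_default_perturbation_preserves_true_volume(self):
        """Ground-truth volume change under repositioning stays within 2%,
        the assumption behind consecutive-day repeatability."""
        rels = []
        for seed in range(20):
            (_, m1), (_, m2) = generate_retest_pair(tiny_spec(seed=seed), TINY_PERT)
            v1, v2 = mask_volume_mm3(m1), mask_volume_mm3(m2)
            rels.append(abs(v2 - v1) / ((v1 + v2) / 2))
        assert max(rels) <= 0.02

    def test_ground_truth_wcv_below_1_5_percent(self):
        tests, retests = [], []
        for seed in range(13):
            (_, m1), (_, m2) = generate_retest_pair(tiny_spec(seed=100 + seed), TINY_PERT)
            tests.append(mask_volume_mm3(m1))
            retests.append(mask_volume_mm3(m2))
        pairs = PairedVolumes(test=tuple(tests), retest=tuple(retests))
        assert wcv(pairs) < 1.5

    def test_retest_noise_is_fresh(self):
        (v1, _), (v2, _) = generate_retest_pair(
            tiny_spec(seed=6),
            RetestPerturbation(max_rotation_deg=0.0, max_translation_voxels=0.0),
        )
        assert not np.array_equal(v1.intensities, v2.intensities)


class TestSimulatedAnnotator:
    def test_identity_model_returns_identical_mask(self):
        _, mask = generate_tibia_phantom(tiny_spec(seed=7))
        out = simulate_annotator(
            mask,
            AnnotatorModel(volume_bias_fraction=0.0, volume_bias_sd=0.0,
                           boundary_jitter_sigma=0.0),
        )
        np.testing.assert_array_equal(out.labels, mask.labels)

    def test_positive_bias_yields_over_segmentation_band(self):
        """Bias +0.14 emulates the second expert; the mean volume error over
        seeds must land in the reported 10-18% over-segmentation band."""
        _, mask = generate_tibia_phantom(tiny_spec(seed=8))
        ves = []
        for seed in range(20):
            out = simulate_annotator(
                mask, AnnotatorModel(volume_bias_fraction=0.14, seed=seed)
            )
            ves.append(100.0 * (out.voxel_count - mask.voxel_count) / mask.voxel_count)
        assert 10.0 <= np.mean(ves) <= 18.0

    def test_output_is_valid_mask_on_same_geometry(self):
        _, mask = generate_tibia_phantom(tiny_spec(seed=9))
        out = simulate_annotator(
            mask,
            AnnotatorModel(volume_bias_fraction=-0.1, boundary_jitter_sigma=2.0, seed=1),
        )
        assert out.geometry == mask.geometry
        assert set(np.unique(out.labels)) <= {0, 1}

    def test_jitter_degrades_overlap_without_volume_shift(self):
        from tibiaseg.metrics import jaccard

        _, mask = generate_tibia_phantom(tiny_spec(seed=10))
        out = simulate_annotator(
            mask,
            AnnotatorModel(volume_bias_fraction=0.0, volume_bias_sd=0.0,
                           boundary_jitter_sigma=1.5, seed=2),
        )
        assert jaccard(out, mask) < 100.0
        ve = 100.0 * (out.voxel_count - mask.voxel_count) / mask.voxel_count
        assert abs(ve) < 1.0  # level-set threshold keeps the volume on target


class TestCohort:
    def test_paper_default_census(self):
        census = cohort_census(plan_cohort(CohortSpec.paper_default()))
        assert census["n_mice"] == 32
        assert census["n_scans"] == 157
        assert census["n_pairs"] == 49
        assert (census["train_scans"], census["val_scans"], census["test_scans"]) == (
            107, 17, 33,
        )
        assert (census["train_pairs"], census["val_pairs"], census["test_pairs"]) == (
            32, 4, 13,
        )

    def test_controls_only_in_train_and_validation(self):
        manifest = plan_cohort(CohortSpec.paper_default())
        controls = manifest[manifest["group"] == "control"]
        assert set(controls["split"]) == {"train", "val"}
        assert len(controls[controls["split"] == "train"]) == 21
        assert len(controls[controls["split"] == "val"]) == 6

    def test_tiny_census_arithmetic(self):
        census = cohort_census(plan_cohort(CohortSpec.tiny()))
        assert census["n_scans"] == 24
        assert census["n_pairs"] == 12

    def test_plan_deterministic(self):
        a = plan_cohort(CohortSpec.paper_default(seed=3))
        b = plan_cohort(CohortSpec.paper_default(seed=3))
        assert a.equals(b)

    def test_growth_trajectories_monotone_and_bounded(self):
        spec = CohortSpec.paper_default(seed=2)
        for mi, plan in enumerate(spec.mice):
            vols = [spec.volume_at(mi, d) for d in plan.timepoints_days]
            assert all(6.5 <= v <= 9.9 for v in vols)
            assert vols == sorted(vols)

    def test_infeasible_pair_schedule_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            MousePlan(
                mouse_id="m1", group="diseased", split="train",
                timepoints_days=(0,), paired_timepoints=(14,),
            )
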