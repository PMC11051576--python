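"""Phantom generator: exact geometry, ground truth, determinism, cohorts."""

import numpy as np
import pandas as pd
import pytest

from avcscore import (
    ConversionModel,
    PhantomSpec,
    make_agreement_pairs,
    make_cect_phantom,
    make_native_phantom,
    make_paired_cohort,
    oracle_agatston,
)

from conftest import basic_spec, random_small_spec


class TestNativePhantom:
    def test_no_lesions_means_no_calcium(self):
        spec = basic_spec(lesions=[], noise_sd=0.0)
        _, truth = make_native_phantom(spec)
        assert truth.true_volume_mm3 == 0.0
        assert truth.true_agatston == 0.0
        assert not truth.calcium_mask.any()

    def test_noiseless_values_are_analytic(self):
        spec = basic_spec(noise_sd=0.0)
        vol, truth = make_native_phantom(spec)
        # lesion voxels carry the peak HU exactly
        assert np.all(vol.voxels[truth.calcium_mask] == 800.0)
        # background voxel far from everything
        assert vol.voxels[0, 0, 0] == spec.background_hu
        # blood pool above the valve region
        k = spec.annulus_slice_index + 20  # 15 mm above the annulus
        i = int(round(spec.lumen_center_mm[0] / spec.pixel_size))
        j = int(round(spec.lumen_center_mm[1] / spec.pixel_size))
        assert vol.voxels[k, i, j] == spec.native_blood_hu

    def test_seeded_render_is_deterministic(self):
        spec = basic_spec(noise_sd=25.0, seed=11)
        v1, _ = make_native_phantom(spec)
        v2, _ = make_native_phantom(spec)
        np.testing.assert_array_equal(v1.voxels, v2.voxels)
        v3, _ = make_native_phantom(basic_spec(noise_sd=25.0, seed=12))
        assert not np.array_equal(v1.voxels, v3.voxels)

    def test_truth_volume_equals_count_times_voxel_volume(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            spec = random_small_spec(rng)
            _, truth = make_native_phantom(spec)
            expected = truth.calcium_mask.sum() * (
                spec.pixel_size**2 * spec.slice_increment
            )
            assert truth.true_volume_mm3 == pytest.approx(expected, abs=1e-12)

    def test_true_volume_monotone_in_lesion_radius(self):
        volumes = []
        for radius in (1.0, 1.5, 2.0, 2.5, 3.0, 3.5):
            spec = basic_spec(
                lesions=[((7.5, 22.0, 22.0), radius, 800.0)], noise_sd=0.0
            )
            _, truth = make_native_phantom(spec)
            volumes.append(truth.true_volume_mm3)
        assert all(b >= a for a, b in zip(volumes, volumes[1:]))
        assert volumes[-1] > volumes[0]

    def test_subthreshold_lesion_absent_from_truth(self):
        spec = basic_spec(
            lesions=[((7.5, 22.0, 22.0), 2.0, 100.0)], noise_sd=0.0
        )
        _, truth = make_native_phantom(spec)
        assert truth.true_volume_mm3 == 0.0


class TestCECTPhantom:
    def test_lesion_above_dynamic_threshold_in_truth(self):
        spec = basic_spec(
            enhancement_hu=350.0, noise_sd=25.0,
            lesions=[((7.5, 22.0, 22.0), 2.0, 800.0)],
        )
        _, truth = make_cect_phantom(spec)
        assert truth.threshold_hu == 350.0 + 4 * 25.0
        assert truth.calcium_mask.any()

    def test_lesion_below_dynamic_threshold_excluded(self):
        spec = basic_spec(
            enhancement_hu=350.0, noise_sd=25.0,
            lesions=[((7.5, 22.0, 22.0), 2.0, 440.0)],
        )
        _, truth = make_cect_phantom(spec)
        assert truth.true_volume_mm3 == 0.0

    def test_distractor_rendered_but_not_truth(self):
        spec = basic_spec(
            noise_sd=0.0,
            distractors=[((30.0, 5.0, 5.0), 2.0, 900.0)],
        )
        vol, truth = make_cect_phantom(spec)
        assert (vol.voxels == 900.0).any()
        assert truth.distractor_mask.any()
        assert not (truth.calcium_mask & truth.distractor_mask).any()
        assert not truth.calcium_mask[truth.distractor_mask].any()

    def test_valve_mask_excludes_distractor(self):
        spec = basic_spec(distractors=[((30.0, 5.0, 5.0), 2.0, 900.0)])
        _, truth = make_cect_phantom(spec)
        assert not (truth.valve_mask & truth.distractor_mask).any()


class TestSpecValidation:
    def test_lesion_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside the grid"):
            basic_spec(lesions=[((7.5, 0.5, 22.0), 2.0, 800.0)])

    def test_lesion_outside_valve_region_rejected(self):
        with pytest.raises(ValueError, match="valve region"):
            basic_spec(lesions=[((30.0, 22.0, 22.0), 2.0, 800.0)])

    def test_distractor_inside_valve_region_rejected(self):
        with pytest.raises(ValueError, match="distractor"):
            basic_spec(distractors=[((7.5, 22.0, 22.0), 2.0, 800.0)])

    def test_grid_too_short_for_reference_roi_rejected(self):
        with pytest.raises(ValueError, match="ROI slice"):
            basic_spec(grid_shape=(30, 80, 80))

    def test_lesion_peak_must_exceed_background(self):
        with pytest.raises(ValueError, match="background"):
            basic_spec(lesions=[((7.5, 22.0, 22.0), 2.0, 10.0)])

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            basic_spec(noise_sd=-1.0)


class TestOracleScorer:
    def test_ten_pixel_single_slab_lesion_scores_ten(self):
        # 10 in-plane pixels of 0.25 mm^2 at 450 HU in one 3 mm slab:
        # area 2.5 mm^2, density weight 4 -> Agatston score 10.0
        spec = PhantomSpec(
            grid_shape=(14, 64, 64),
            pixel_size=0.5,
            slice_increment=3.0,
            slice_thickness=3.0,
            lumen_center_mm=(16.0, 16.0),
            lumen_radius_mm=14.0,
            lesions=[((3.0, 16.0, 16.1), 0.9, 450.0)],
            noise_sd=0.0,
            annulus_slice_index=1,
            background_hu=0.0,
        )
        vol, truth = make_native_phantom(spec)
        assert truth.calcium_mask.sum() == 10
        assert truth.true_agatston == 10.0
        score, volume, lesions = oracle_agatston(vol.voxels, 0.5, 3.0)
        assert score == 10.0
        assert len(lesions) == 1
        assert lesions[0]["weight"] == 4
        assert volume == pytest.approx(10 * 0.25 * 3.0)

    def test_oracle_rejects_non_commensurate_slab(self):
        with pytest.raises(ValueError, match="multiple"):
            oracle_agatston(np.zeros((4, 4, 4)), 0.5, 0.75, slab_mm=2.5)


class TestPairedCohort:
    MODEL = ConversionModel(intercept=691.0, slope=1.83)

    def test_noise_free_points_lie_on_the_line(self):
        df = make_paired_cohort(10, self.MODEL, noise_sd=0.0, seed=1)
        np.testing.assert_allclose(
            df["native_agatston"],
            691.0 + 1.83 * df["cect_volume_mm3"],
            rtol=1e-12,
        )

    def test_reproducible_under_seed(self):
        a = make_paired_cohort(8, self.MODEL, seed=99)
        b = make_paired_cohort(8, self.MODEL, seed=99)
        pd.testing.assert_frame_equal(a, b)

    def test_volumes_respect_requested_range(self):
        df = make_paired_cohort(200, self.MODEL, (300.0, 2500.0), 400.0, seed=2)
        assert df["cect_volume_mm3"].between(300.0, 2500.0).all()

    def test_underdetermined_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            make_paired_cohort(2, self.MODEL, seed=0)


class TestAgreementPairs:
    def test_icc_one_gives_identical_pairs(self):
        a, b = make_agreement_pairs(10, icc=1.0, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_reproducible_and_seed_sensitive(self):
        a1, b1 = make_agreement_pairs(10, icc=0.9, seed=4)
        a2, b2 = make_agreement_pairs(10, icc=0.9, seed=4)
        a3, _ = make_agreement_pairs(10, icc=0.9, seed=5)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(b1, b2)
        assert not np.array_equal(a1, a3)

    def test_invalid_icc_rejected(self):
        with pytest.raises(ValueError, match="icc"):
            make_agreement_pairs(10, icc=0.0, seed=0)
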