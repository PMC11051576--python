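"""Native Agatston scoring: slabs, weights, lesions, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avcscore import (
    CTVolume,
    agatston_score,
    apply_exclusion,
    density_weight,
    detect_lesions,
    make_native_phantom,
    oracle_agatston,
    resample_slabs,
    score_native,
)

from conftest import basic_spec, flat_native_volume, random_small_spec


def _thin_volume(voxels, inc=0.75, px=0.5):
    return CTVolume(
        voxels=np.asarray(voxels, dtype=float),
        pixel_size=px,
        slice_increment=inc,
        slice_thickness=1.0,
        modality="native",
    )


class TestResampleSlabs:
    def test_uniform_volume_keeps_its_hu(self):
        vol = _thin_volume(np.full((12, 4, 4), 215.0))
        slabs = resample_slabs(vol, 3.0)
        assert slabs.n_slices == 3
        assert np.all(slabs.voxels == 215.0)
        assert slabs.slice_increment == 3.0

    def test_groups_of_four_are_averaged(self):
        voxels = np.zeros((12, 1, 1))
        voxels[:, 0, 0] = np.arange(12, dtype=float)
        slabs = resample_slabs(_thin_volume(voxels), 3.0)
        np.testing.assert_allclose(slabs.voxels[:, 0, 0], [1.5, 5.5, 9.5])

    def test_trailing_partial_group_becomes_thin_slab(self):
        voxels = np.zeros((10, 1, 1))
        voxels[:, 0, 0] = np.arange(10, dtype=float)
        slabs = resample_slabs(_thin_volume(voxels), 3.0)
        assert slabs.n_slices == 3
        np.testing.assert_allclose(slabs.voxels[:, 0, 0], [1.5, 5.5, 8.5])

    def test_non_commensurate_slab_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            resample_slabs(_thin_volume(np.zeros((12, 2, 2))), 2.5)


class TestDensityWeight:
    @pytest.mark.parametrize(
        "max_hu,expected",
        [(130, 1), (199.9, 1), (200, 2), (299, 2), (300, 3), (399, 3),
         (400, 4), (2500, 4)],
    )
    def test_bracket_table(self, max_hu, expected):
        assert density_weight(max_hu) == expected

    def test_below_calcium_threshold_rejected(self):
        with pytest.raises(ValueError, match="130"):
            density_weight(129)

    @given(st.floats(min_value=130, max_value=5000))
    @settings(deadline=None, max_examples=50)
    def test_weight_monotone_in_max_hu(self, hu):
        assert density_weight(hu) <= density_weight(hu + 50.0)


class TestDetectLesions:
    def test_subthreshold_plane_has_no_lesions(self):
        vol = flat_native_volume(np.full((8, 8), 129.0))
        assert detect_lesions(vol) == []

    def test_exactly_130_is_included(self):
        plane = np.zeros((8, 8))
        plane[2:4, 2:4] = 130.0  # 4 px -> 1 mm^2, at min area
        vol = flat_native_volume(plane)
        lesions = detect_lesions(vol)
        assert len(lesions) == 1
        assert lesions[0].weight == 1
        assert lesions[0].area_mm2 == pytest.approx(1.0)

    def test_ten_pixel_component_at_450(self):
        plane = np.zeros((8, 8))
        plane[2, 2:7] = 450.0
        plane[3, 2:7] = 450.0  # 10 pixels, 8-connected
        vol = flat_native_volume(plane)
        lesions = detect_lesions(vol)
        assert len(lesions) == 1
        assert lesions[0].n_pixels == 10
        assert lesions[0].area_mm2 == pytest.approx(2.5)
        assert lesions[0].weight == 4
        assert lesions[0].score == pytest.approx(10.0)

    def test_component_below_min_area_discarded(self):
        plane = np.zeros((8, 8))
        plane[2, 2:5] = 450.0  # 3 px * 0.25 mm^2 = 0.75 mm^2 < 1 mm^2
        vol = flat_native_volume(plane)
        assert detect_lesions(vol) == []

    def test_diagonal_pixels_are_one_component(self):
        plane = np.zeros((8, 8))
        for k in range(4):
            plane[2 + k, 2 + k] = 300.0
        vol = flat_native_volume(plane)
        assert len(detect_lesions(vol, min_area_mm2=0.25)) == 1

    def test_contrast_volume_rejected(self):
        vol = flat_native_volume(np.zeros((4, 4)))
        vol.modality = "contrast"
        with pytest.raises(ValueError, match="native"):
            detect_lesions(vol)


class TestAgatstonScore:
    def test_empty_lesion_list_scores_zero(self):
        vol = flat_native_volume(np.zeros((4, 4)))
        result = agatston_score([], vol)
        assert result.total_score == 0.0
        assert result.volume_mm3 == 0.0

    def test_two_identical_disjoint_lesions_double_the_score(self):
        plane_one = np.zeros((16, 16))
        plane_one[2:4, 2:6] = 450.0
        plane_two = plane_one.copy()
        plane_two[10:12, 10:14] = 450.0
        r1 = score_native(flat_native_volume(plane_one))
        r2 = score_native(flat_native_volume(plane_two))
        assert r2.total_score == pytest.approx(2 * r1.total_score)
        assert r2.volume_mm3 == pytest.approx(2 * r1.volume_mm3)

    def test_volume_uses_increment_on_thin_slices(self):
        voxels = np.zeros((4, 8, 8))
        voxels[:, 2:4, 2:4] = 450.0  # 4 px x 4 slices
        vol = _thin_volume(voxels, inc=0.75)
        result = score_native(vol)
        assert result.volume_mm3 == pytest.approx(16 * 0.25 * 0.75)


class TestExclusion:
    def test_mask_removes_distractor_from_lesion_list(self):
        plane = np.zeros((16, 16))
        plane[2:4, 2:6] = 450.0  # valve lesion
        plane[10:12, 10:14] = 500.0  # distractor
        vol = flat_native_volume(plane)
        mask = np.zeros(vol.shape, dtype=bool)
        mask[:, 8:, 8:] = True
        result = score_native(vol, exclusion_mask=mask)
        assert len(result.lesions) == 1
        assert result.lesions[0].max_hu == 450.0

    def test_empty_mask_is_identity(self):
        plane = np.zeros((8, 8))
        plane[2:4, 2:6] = 450.0
        vol = flat_native_volume(plane)
        base = score_native(vol)
        masked = score_native(vol, exclusion_mask=np.zeros(vol.shape, bool))
        assert masked.total_score == base.total_score

    def test_full_mask_annihilates_score(self):
        plane = np.full((8, 8), 450.0)
        vol = flat_native_volume(plane)
        result = score_native(vol, exclusion_mask=np.ones(vol.shape, bool))
        assert result.total_score == 0.0
        assert result.volume_mm3 == 0.0

    def test_shape_mismatch_rejected(self):
        vol = flat_native_volume(np.zeros((8, 8)))
        with pytest.raises(ValueError, match="shape"):
            apply_exclusion(vol, np.zeros((2, 2, 2), bool))


class TestOracleEquivalence:
    def test_production_matches_brute_force_on_random_phantoms(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            spec = random_small_spec(rng)
            vol, _ = make_native_phantom(spec)
            prod = score_native(vol)
            score, volume, lesions = oracle_agatston(
                vol.voxels, spec.pixel_size, spec.slice_increment
            )
            assert prod.total_score == pytest.approx(score, abs=1e-9)
            assert prod.volume_mm3 == pytest.approx(volume, abs=1e-9)
            assert len(prod.lesions) == len(lesions)


class TestInvariances:
    def test_score_invariant_under_inplane_rotation_and_slice_reversal(self):
        spec = basic_spec(
            grid_shape=(56, 80, 80),  # 56 slices -> whole number of slabs
            noise_sd=20.0,
            seed=3,
            lesions=[((7.5, 22.0, 22.0), 2.5, 700.0)],
        )
        vol, _ = make_native_phantom(spec)
        base = score_native(vol)
        rotated = vol.with_voxels(np.rot90(vol.voxels, axes=(1, 2)))
        reversed_ = vol.with_voxels(vol.voxels[::-1])
        assert score_native(rotated).total_score == pytest.approx(base.total_score)
        assert score_native(reversed_).total_score == pytest.approx(base.total_score)
        assert score_native(rotated).volume_mm3 == pytest.approx(base.volume_mm3)

    def test_raising_lesion_hu_never_decreases_score(self):
        scores = []
        for peak in (150.0, 250.0, 350.0, 450.0, 800.0):
            spec = basic_spec(
                lesions=[((7.5, 22.0, 22.0), 2.0, peak)], noise_sd=0.0
            )
            vol, _ = make_native_phantom(spec)
            scores.append(score_native(vol).total_score)
        assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_lowering_threshold_never_decreases_volume(self):
        spec = basic_spec(noise_sd=15.0, seed=9)
        vol, _ = make_native_phantom(spec)
        volumes = [
            score_native(vol, threshold_hu=t).volume_mm3
            for t in (400.0, 300.0, 200.0, 130.0)
        ]
        assert all(b >= a for a, b in zip(volumes, volumes[1:]))
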