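import numpy as np
import pytest

from marrowpet.io import BinaryMask, SUVVolume
from marrowpet.phantom import PhantomSpec, ScannerEffect, generate_patient_volume, generate_pelvis_mask
from marrowpet.radiomics import (
    ALL_FEATURES,
    OFFSETS_3D,
    PEAK_RADIUS_MM,
    TEXTURE_FEATURES,
    DiscretizedVolume,
    EmptyCooccurrenceError,
    GLCM,
    RadiomicsConfig,
    build_glcm,
    discretize,
    extract_features,
    haralick_features,
    suv_metrics,
)
from marrowpet.segmentation import segment_mtv

from oracles import glcm_oracle, haralick_oracle, sphere_peak_oracle

SPACING = (5.5, 5.5, 3.3)


def _vol(arr, spacing=SPACING):
    return SUVVolume(np.asarray(arr, dtype=np.float32), spacing)


def _mask(arr, spacing=SPACING):
    return BinaryMask(np.asarray(arr, dtype=np.uint8), spacing)


class TestSUVMetrics:
    def test_constant_region(self):
        vals = np.full((8, 8, 8), 3.0)
        mask = np.ones((8, 8, 8), dtype=np.uint8)
        assert suv_metrics(_vol(vals), _mask(mask)) == pytest.approx((3.0, 3.0, 3.0))

    def test_mean_and_max_two_voxels(self):
        vals = np.zeros((4, 4, 4))
        vals[0, 0, 0], vals[1, 0, 0] = 2.0, 4.0
        mask = np.zeros((4, 4, 4), dtype=np.uint8)
        mask[0, 0, 0] = mask[1, 0, 0] = 1
        mx, mn, _ = suv_metrics(_vol(vals), _mask(mask))
        assert (mx, mn) == pytest.approx((4.0, 3.0))

    def test_peak_matches_sphere_enumeration(self, rng):
        vals = rng.random((10, 10, 8)).astype(np.float32) * 2
        center = (4, 5, 3)
        vals[center] = 5.0  # unique max
        mask = np.zeros(vals.shape, dtype=np.uint8)
        mask[center] = 1
        _, _, peak = suv_metrics(_vol(vals), _mask(mask))
        expected = sphere_peak_oracle(vals, SPACING, center, PEAK_RADIUS_MM)
        assert peak == pytest.approx(expected, abs=1e-6)

    def test_peak_clipped_at_image_boundary(self, rng):
        vals = rng.random((6, 6, 4)).astype(np.float32)
        vals[0, 0, 0] = 9.0
        mask = np.zeros(vals.shape, dtype=np.uint8)
        mask[0, 0, 0] = 1
        _, _, peak = suv_metrics(_vol(vals), _mask(mask))
        expected = sphere_peak_oracle(vals, SPACING, (0, 0, 0), PEAK_RADIUS_MM)
        assert peak == pytest.approx(expected, abs=1e-6)

    def test_ordering_invariants(self, rng):
        vals = rng.random((8, 8, 6)) * 6
        mask = np.ones(vals.shape, dtype=np.uint8)
        mx, mn, pk = suv_metrics(_vol(vals), _mask(mask))
        assert mn <= mx and pk <= mx

    def test_empty_mtv_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            suv_metrics(_vol(np.ones((3, 3, 3))), _mask(np.zeros((3, 3, 3))))


class TestDiscretize:
    def test_uniform_partition(self):
        vals = np.zeros((4, 1, 1))
        vals[:, 0, 0] = [0, 1, 2, 3]
        mask = np.ones((4, 1, 1), dtype=np.uint8)
        d = discretize(_vol(vals), _mask(mask), "fixed-bin-number", 4)
        assert d.levels[:, 0, 0].tolist() == [1, 2, 3, 4]

    def test_fixed_width_floor_rule(self):
        vals = np.zeros((3, 1, 1))
        vals[:, 0, 0] = [1.0, 1.2, 2.6]
        mask = np.ones((3, 1, 1), dtype=np.uint8)
        d = discretize(_vol(vals), _mask(mask), "fixed-bin-width", 1.0)
        assert d.levels[:, 0, 0].tolist() == [1, 1, 2]

    def test_constant_region_maps_to_level_one(self):
        vals = np.full((3, 3, 3), 2.5)
        mask = np.ones((3, 3, 3), dtype=np.uint8)
        d = discretize(_vol(vals), _mask(mask), "fixed-bin-number", 25)
        assert set(d.levels[mask.astype(bool)]) == {1}

    def test_levels_bounded_and_monotone(self, rng):
        vals = rng.random((6, 6, 4)) * 10
        mask = np.ones(vals.shape, dtype=np.uint8)
        d = discretize(_vol(vals), _mask(mask), "fixed-bin-number", 25)
        inmask = d.levels[mask.astype(bool)]
        assert inmask.min() >= 1 and inmask.max() <= 25
        order = np.argsort(vals[mask.astype(bool)])
        assert np.all(np.diff(inmask[order]) >= 0)

    def test_outside_mask_is_zero(self, rng):
        vals = rng.random((5, 5, 5))
        mask = np.zeros(vals.shape, dtype=np.uint8)
        mask[1:4, 1:4, 1:4] = 1
        d = discretize(_vol(vals), _mask(mask), "fixed-bin-number", 8)
        assert (d.levels[~mask.astype(bool)] == 0).all()


class TestBuildGLCM:
    def test_constant_block_single_entry(self):
        levels = np.zeros((3, 3, 3), dtype=np.int32)
        levels[:2, :2, :2] = 1
        g = build_glcm(DiscretizedVolume(levels, 1, "fixed-bin-number", 1), (1, 0, 0))
        assert g.P.shape == (1, 1) and g.P[0, 0] == pytest.approx(1.0)

    def test_alternating_strip(self):
        levels = np.zeros((4, 1, 1), dtype=np.int32)
        levels[:, 0, 0] = [1, 2, 1, 2]
        g = build_glcm(DiscretizedVolume(levels, 2, "fixed-bin-number", 2), (1, 0, 0))
        assert g.P[0, 1] == pytest.approx(0.5)
        assert g.P[1, 0] == pytest.approx(0.5)
        assert g.P[0, 0] == g.P[1, 1] == 0

    @pytest.mark.parametrize("offset", [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, -1, 0), (1, 1, 1)])
    def test_matches_exhaustive_enumeration(self, rng, offset):
        levels = rng.integers(0, 5, size=(4, 4, 3)).astype(np.int32)
        if not ((levels > 0).sum() > 4):
            levels[0, 0, 0] = 1
        d = DiscretizedVolume(levels, 4, "fixed-bin-number", 4)
        g = build_glcm(d, offset)
        expected = glcm_oracle(levels, 4, offset)
        assert np.allclose(g.P, expected, atol=1e-12)

    def test_no_pair_raises(self):
        levels = np.zeros((3, 3, 3), dtype=np.int32)
        levels[0, 0, 0] = 1  # isolated voxel
        with pytest.raises(EmptyCooccurrenceError):
            build_glcm(DiscretizedVolume(levels, 1, "fixed-bin-number", 1), (1, 0, 0))

    def test_invalid_offsets_rejected(self):
        d = DiscretizedVolume(np.ones((3, 3, 3), dtype=np.int32), 1, "fixed-bin-number", 1)
        with pytest.raises(ValueError):
            build_glcm(d, (0, 0, 0))
        with pytest.raises(ValueError):
            build_glcm(d, (2, 0, 0))


class TestHaralick:
    def test_degenerate_single_entry(self):
        f = haralick_features(GLCM(np.array([[1.0]])))
        assert f["angular_second_moment"] == 1
        assert f["entropy"] == 0
        assert f["contrast"] == 0
        assert f["homogeneity"] == 1
        assert f["inverse_difference_moment"] == 1
        assert f["maximum_probability"] == 1
        assert f["cluster_shade"] == 0
        assert f["imc2"] == 0
        assert f["correlation"] == 1  # single gray level: perfectly predictable

    def test_hand_computed_two_level_matrix(self):
        P = np.array([[0.0, 0.5], [0.5, 0.0]])
        f = haralick_features(GLCM(P))
        assert f["contrast"] == pytest.approx(1.0)
        assert f["angular_second_moment"] == pytest.approx(0.5)
        assert f["entropy"] == pytest.approx(np.log(2))
        assert f["sum_average"] == pytest.approx(3.0)
        assert f["maximum_probability"] == pytest.approx(0.5)

    def test_random_matrix_matches_oracle(self, rng):
        for _ in range(10):
            A = rng.random((6, 6))
            P = (A + A.T) / (A + A.T).sum()
            ours = haralick_features(GLCM(P))
            theirs = haralick_oracle(P)
            for k in TEXTURE_FEATURES:
                assert ours[k] == pytest.approx(theirs[k], abs=1e-10), k

    def test_log_base_affects_entropy_family_only(self, rng):
        A = rng.random((5, 5))
        P = (A + A.T) / (A + A.T).sum()
        nat = haralick_features(GLCM(P), "natural")
        b2 = haralick_features(GLCM(P), "base2")
        assert b2["entropy"] == pytest.approx(nat["entropy"] / np.log(2))
        assert b2["contrast"] == pytest.approx(nat["contrast"])
        assert b2["sum_average"] == pytest.approx(nat["sum_average"])

    def test_gray_level_permutation_invariance(self, rng):
        """Reversing the gray-level order preserves co-occurrence multiset
        statistics: entropy, ASM and maximum probability are unchanged."""
        A = rng.random((6, 6))
        P = (A + A.T) / (A + A.T).sum()
        Pr = P[::-1, ::-1]  # relabel i -> Ng+1-i
        f1, f2 = haralick_features(GLCM(P)), haralick_features(GLCM(Pr))
        for k in ("entropy", "angular_second_moment", "maximum_probability"):
            assert f1[k] == pytest.approx(f2[k], abs=1e-12)


class TestExtractFeatures:
    def test_record_contains_19_numeric_features(self, rng):
        vals = rng.random((8, 8, 6)) * 4 + 1
        mask = np.ones(vals.shape, dtype=np.uint8)
        f = extract_features(_vol(vals), _mask(mask))
        assert list(f) == ALL_FEATURES
        assert all(np.isfinite(v) for v in f.values())

    def test_isotropic_constant_region_direction_independent(self):
        vals = np.full((6, 6, 6), 2.0)
        mask = np.ones(vals.shape, dtype=np.uint8)
        f = extract_features(_vol(vals, (1, 1, 1)), _mask(mask, (1, 1, 1)))
        d = discretize(_vol(vals, (1, 1, 1)), _mask(mask, (1, 1, 1)), "fixed-bin-number", 25)
        single = haralick_features(build_glcm(d, (1, 0, 0)))
        for k in TEXTURE_FEATURES:
            assert f[k] == pytest.approx(single[k], abs=1e-12)

    def test_direction_average_matches_per_direction_oracle(self, rng):
        vals = rng.random((6, 6, 5)) * 3
        # stripes along x to force anisotropy
        vals += np.arange(6)[:, None, None] % 2
        mask = np.ones(vals.shape, dtype=np.uint8)
        f = extract_features(_vol(vals), _mask(mask))
        d = discretize(_vol(vals), _mask(mask), "fixed-bin-number", 25)
        per_dir = [haralick_features(build_glcm(d, off)) for off in OFFSETS_3D]
        expected = np.mean([p["contrast"] for p in per_dir])
        assert f["contrast"] == pytest.approx(expected, abs=1e-10)
        spread = np.ptp([p["contrast"] for p in per_dir])
        assert spread > 0  # directions genuinely differ on the striped phantom

    def test_single_voxel_mtv_rejected(self):
        vals = np.ones((4, 4, 4))
        mask = np.zeros(vals.shape, dtype=np.uint8)
        mask[1, 1, 1] = 1
        with pytest.raises(ValueError, match="too small"):
            extract_features(_vol(vals), _mask(mask))

    def test_rotation_consistency_about_axial_axis(self, rng):
        """A 90-degree in-plane rotation permutes directions but leaves the
        13-direction average unchanged (in-plane spacing is isotropic)."""
        vals = (rng.random((7, 7, 5)) * 4).astype(np.float32)
        mask_arr = np.zeros(vals.shape, dtype=np.uint8)
        mask_arr[1:6, 1:6, 1:4] = 1
        rot_vals = np.rot90(vals, k=1, axes=(0, 1)).copy()
        rot_mask = np.rot90(mask_arr, k=1, axes=(0, 1)).copy()
        f1 = extract_features(_vol(vals), _mask(mask_arr))
        f2 = extract_features(_vol(rot_vals), _mask(rot_mask))
        for k in TEXTURE_FEATURES:
            assert f1[k] == pytest.approx(f2[k], abs=1e-9), k

    def test_heterogeneity_monotonicity_over_random_fields(self):
        """Doubling the texture field SD raises mean entropy and lowers mean
        angular second moment over 50 seeded small phantoms.  Measured with
        fixed-bin-width discretization (absolute SUV bins): fixed-bin-number
        renormalizes each patient's range and is amplitude-invariant by
        design."""
        config = RadiomicsConfig(mode="fixed-bin-width", bin_width=0.05)
        spec_lo = PhantomSpec(grid_shape=(24, 24, 12), texture_sd=(0.15, 0.15),
                              noise_sd=0.0)
        spec_hi = PhantomSpec(grid_shape=(24, 24, 12), texture_sd=(0.30, 0.30),
                              noise_sd=0.0)
        eff = ScannerEffect("S0", 0.0, 1.0, 0.0, 0.0)
        ent, asm = {"lo": [], "hi": []}, {"lo": [], "hi": []}
        for seed in range(50):
            for tag, spec in (("lo", spec_lo), ("hi", spec_hi)):
                vol = generate_patient_volume(spec, False, 0.0, eff, seed=seed)
                mask = generate_pelvis_mask(spec)
                mtv = segment_mtv(vol, mask, 0.41)
                f = extract_features(vol, mtv.mtv_mask, config)
                ent[tag].append(f["entropy"])
                asm[tag].append(f["angular_second_moment"])
        assert np.mean(ent["hi"]) > np.mean(ent["lo"])
        assert np.mean(asm["hi"]) < np.mean(asm["lo"])

    def test_merged_direction_mode_runs(self, rng):
        vals = rng.random((6, 6, 5)) * 3
        mask = np.ones(vals.shape, dtype=np.uint8)
        f = extract_features(_vol(vals), _mask(mask), RadiomicsConfig(merge_directions=True))
        assert set(f) == set(ALL_FEATURES)
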