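"""Radiomic feature extraction: discretization, first-order, shape, texture."""

import math

import numpy as np
import pytest

from petfuse.errors import DegenerateInputError, ParameterError
from petfuse.features import (
    DIRECTIONS_13,
    DiscretizationConfig,
    FEATURE_NAMES,
    RadiomicsConfig,
    discretize,
    extract_all,
    first_order_features,
    gldm_matrix,
    glcm_features,
    glcm_matrices,
    glrlm_features,
    glrlm_matrix_one_direction,
    glszm_features,
    glszm_matrix,
    peritumoral_mask,
    shape_features,
)
from petfuse.imaging import LesionMask, Volume3D

from oracles import NEIGHBORS_26


def vol(data, spacing=(1, 1, 1)):
    return Volume3D(np.asarray(data, dtype=float), spacing)


def full_mask(shape, spacing=(1, 1, 1)):
    return LesionMask(np.ones(shape, dtype=bool), "GTVp", spacing)


def strip_levels(values):
    """A 1-D strip of gray levels along the x axis, as an (n,1,1) grid."""
    return np.asarray(values, dtype=np.int32).reshape(-1, 1, 1)


class TestDiscretize:
    def test_constant_region_single_level(self):
        v = vol(np.full((3, 3, 3), 7.0))
        levels, ng = discretize(v, full_mask((3, 3, 3)))
        assert ng == 1
        assert set(np.unique(levels)) == {1}

    def test_two_point_split(self):
        data = np.zeros((2, 1, 1))
        data[1] = 10.0
        levels, ng = discretize(vol(data), full_mask((2, 1, 1)),
                                DiscretizationConfig("fixed_bin_count", n_bins=2))
        assert ng == 2
        assert levels.ravel().tolist() == [1, 2]

    def test_fixed_bin_width_hand_case(self):
        data = np.arange(10.0).reshape(10, 1, 1)
        levels, ng = discretize(
            vol(data), full_mask((10, 1, 1)),
            DiscretizationConfig("fixed_bin_width", bin_width=2.5),
        )
        assert levels.ravel().tolist() == [1, 1, 1, 2, 2, 3, 3, 3, 4, 4]
        assert ng == 4

    def test_empty_mask_rejected(self):
        v = vol(np.zeros((3, 3, 3)))
        with pytest.raises(DegenerateInputError):
            discretize(v, LesionMask(np.zeros((3, 3, 3)), "GTVp", (1, 1, 1)))

    def test_levels_cover_1_to_ng(self, rng):
        data = rng.normal(size=(6, 6, 6))
        mask = LesionMask(rng.random((6, 6, 6)) > 0.3, "GTVp", (1, 1, 1))
        levels, ng = discretize(vol(data), mask, DiscretizationConfig(n_bins=8))
        inmask = levels[mask.data]
        assert inmask.min() == 1 and inmask.max() == ng == 8
        assert (levels[~mask.data] == 0).all()


class TestFirstOrder:
    def test_constant_region(self):
        feats = first_order_features(vol(np.full((3, 3, 3), 4.0)), full_mask((3, 3, 3)))
        assert feats["mean"] == 4.0
        assert feats["variance"] == 0.0
        assert feats["entropy"] == 0.0

    def test_hand_computed_moments(self):
        data = np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1)
        feats = first_order_features(vol(data), full_mask((4, 1, 1)))
        assert feats["mean"] == pytest.approx(2.5)
        assert feats["variance"] == pytest.approx(1.25)
        assert feats["energy"] == pytest.approx(1 + 4 + 9 + 16)
        assert feats["range"] == 3.0

    def test_symmetric_skewness_zero(self):
        data = np.array([-3.0, -1.0, 0.0, 0.0, 1.0, 3.0]).reshape(6, 1, 1)
        feats = first_order_features(vol(data), full_mask((6, 1, 1)))
        assert abs(feats["skewness"]) < 1e-10

    def test_shift_moves_mean_not_variance(self, rng):
        data = rng.normal(size=(5, 5, 5))
        m = full_mask((5, 5, 5))
        a = first_order_features(vol(data), m)
        b = first_order_features(vol(data + 100.0), m)
        assert b["mean"] == pytest.approx(a["mean"] + 100.0)
        assert b["variance"] == pytest.approx(a["variance"])


class TestShape:
    def test_single_voxel(self):
        data = np.zeros((3, 3, 3), dtype=bool)
        data[1, 1, 1] = True
        feats = shape_features(LesionMask(data, "GTVp", (1, 1, 1)))
        assert feats["volume_mm3"] == 1.0
        assert feats["surface_mm2"] == 6.0
        assert feats["max_diameter_mm"] == 0.0

    def test_two_voxel_block(self):
        data = np.zeros((4, 3, 3), dtype=bool)
        data[1:3, 1, 1] = True
        feats = shape_features(LesionMask(data, "GTVp", (1, 1, 1)))
        assert feats["volume_mm3"] == 2.0
        assert feats["surface_mm2"] == 10.0
        assert feats["max_diameter_mm"] == pytest.approx(1.0)

    def test_digital_ball_approaches_analytic_volume(self):
        r = 10.0
        idx = np.indices((25, 25, 25))
        dist2 = sum((c - 12.0) ** 2 for c in idx)
        mask = LesionMask(dist2 <= r * r, "GTVp", (1, 1, 1))
        feats = shape_features(mask)
        analytic = 4.0 / 3.0 * math.pi * r**3
        assert feats["volume_mm3"] == pytest.approx(analytic, rel=0.05)
        assert 0 < feats["sphericity"] <= 1.05
        assert feats["elongation"] == pytest.approx(1.0, abs=0.05)

    def test_spacing_aware_volume(self):
        data = np.ones((2, 2, 2), dtype=bool)
        feats = shape_features(LesionMask(data, "GTVp", (1.0, 2.0, 3.0)))
        assert feats["volume_mm3"] == pytest.approx(8 * 6.0)
        assert feats["z_extent_mm"] == pytest.approx(6.0)


class TestGLCM:
    def test_constant_region(self):
        levels = np.ones((3, 3, 3), dtype=np.int32)
        feats = glcm_features(levels, 1)
        assert feats["contrast"] == 0.0
        assert feats["joint_energy"] == 1.0
        assert feats["joint_entropy"] == 0.0
        assert math.isnan(feats["correlation"])

    def test_alternating_strip_hand_counts(self):
        levels = strip_levels([1, 2, 1, 2])
        mats = glcm_matrices(levels, 2)
        x_dir = [k for k, d in enumerate(DIRECTIONS_13) if tuple(map(abs, d)) == (1, 0, 0)][0]
        m = mats[x_dir]
        assert m[0, 1] == 3 and m[1, 0] == 3
        assert m[0, 0] == 0 and m[1, 1] == 0
        p = m / m.sum()
        contrast = sum(p[i, j] * (i - j) ** 2 for i in range(2) for j in range(2))
        assert contrast == pytest.approx(1.0)

    def test_normalized_matrix_sums_to_one(self, rng):
        levels = np.zeros((5, 5, 5), dtype=np.int32)
        mask = rng.random((5, 5, 5)) > 0.4
        levels[mask] = rng.integers(1, 5, size=int(mask.sum()))
        for m in glcm_matrices(levels, 4):
            if m.sum() > 0:
                assert (m / m.sum()).sum() == pytest.approx(1.0)

    def test_symmetric_matrix_equals_transpose(self, rng):
        levels = rng.integers(1, 6, size=(4, 4, 4)).astype(np.int32)
        for m in glcm_matrices(levels, 5, symmetric=True):
            np.testing.assert_array_equal(m, m.T)


class TestGLRLM:
    def test_uniform_strip_single_run(self):
        levels = strip_levels([1, 1, 1])
        mat = glrlm_matrix_one_direction(levels, 1, (1, 0, 0))
        assert mat.shape == (1, 3)
        assert mat[0, 2] == 1 and mat[0, :2].sum() == 0
        # run percentage along this direction: 1 run / 3 voxels
        assert mat.sum() / 3 == pytest.approx(1 / 3)

    def test_all_singleton_runs(self):
        levels = strip_levels([1, 2, 3])
        feats = glrlm_features(levels, 3)
        assert feats["short_run_emphasis"] == pytest.approx(1.0)

    def test_run_length_conservation_per_direction(self, rng):
        levels = np.zeros((5, 5, 5), dtype=np.int32)
        mask = rng.random((5, 5, 5)) > 0.35
        levels[mask] = rng.integers(1, 4, size=int(mask.sum()))
        n_vox = int(mask.sum())
        for d in DIRECTIONS_13:
            mat = glrlm_matrix_one_direction(levels, 3, d)
            r = np.arange(1, mat.shape[1] + 1)
            assert (mat * r).sum() == n_vox


class TestGLSZM:
    def test_constant_cube_single_zone(self):
        levels = np.ones((3, 3, 3), dtype=np.int32)
        mat = glszm_matrix(levels, 1)
        assert mat[0, 26] == 1 and mat.sum() == 1
        feats = glszm_features(levels, 1)
        assert feats["zone_percentage"] == pytest.approx(1 / 27)

    def test_diagonal_voxels_form_one_zone(self):
        levels = np.zeros((2, 2, 2), dtype=np.int32)
        levels[0, 0, 0] = 1
        levels[1, 1, 1] = 1
        mat = glszm_matrix(levels, 1)
        assert mat[0, 1] == 1 and mat.sum() == 1

    def test_zone_size_conservation(self, rng):
        levels = np.zeros((6, 6, 6), dtype=np.int32)
        mask = rng.random((6, 6, 6)) > 0.4
        levels[mask] = rng.integers(1, 4, size=int(mask.sum()))
        mat = glszm_matrix(levels, 3)
        s = np.arange(1, mat.shape[1] + 1)
        assert (mat * s).sum() == mask.sum()


class TestGLDM:
    def test_constant_cube_center_dependence(self):
        levels = np.ones((3, 3, 3), dtype=np.int32)
        mat = gldm_matrix(levels, 1)
        assert mat[0, 26] == 1  # the center voxel has all 26 neighbours
        assert mat.sum() == 27

    def test_single_voxel(self):
        levels = np.zeros((3, 3, 3), dtype=np.int32)
        levels[1, 1, 1] = 1
        mat = gldm_matrix(levels, 1)
        assert mat[0, 0] == 1 and mat.sum() == 1

    def test_total_equals_voxel_count(self, rng):
        levels = np.zeros((5, 5, 5), dtype=np.int32)
        mask = rng.random((5, 5, 5)) > 0.3
        levels[mask] = rng.integers(1, 5, size=int(mask.sum()))
        assert gldm_matrix(levels, 4).sum() == mask.sum()


class TestPeritumoral:
    def test_r0_inclusive_identity(self, ball_mask):
        out = peritumoral_mask(ball_mask, 0.0)
        np.testing.assert_array_equal(out.data, ball_mask.data)

    def test_single_voxel_unit_ball_is_plus_shape(self):
        data = np.zeros((5, 5, 5), dtype=bool)
        data[2, 2, 2] = True
        out = peritumoral_mask(LesionMask(data, "GTVp", (1, 1, 1)), 1.0)
        assert out.voxel_count == 7
        for d in NEIGHBORS_26:
            p = (2 + d[0], 2 + d[1], 2 + d[2])
            expected = sum(abs(c) for c in d) == 1
            assert out.data[p] == expected

    def test_nested_growth(self, ball_mask):
        a = peritumoral_mask(ball_mask, 1.0)
        b = peritumoral_mask(ball_mask, 2.0)
        assert np.all(b.data[a.data])

    def test_spacing_aware_dilation(self):
        data = np.zeros((5, 5, 5), dtype=bool)
        data[2, 2, 2] = True
        out = peritumoral_mask(LesionMask(data, "GTVp", (1.0, 1.0, 3.0)), 1.0)
        assert not out.data[2, 2, 1] and not out.data[2, 2, 3]  # 3 mm away in z
        assert out.data[1, 2, 2] and out.data[3, 2, 2]

    def test_ring_excludes_tumor(self, ball_mask):
        ring = peritumoral_mask(ball_mask, 2.0, mode="ring")
        assert not np.any(ring.data & ball_mask.data)
        with pytest.raises(DegenerateInputError):
            peritumoral_mask(ball_mask, 0.0, mode="ring")

    def test_negative_radius_rejected(self, ball_mask):
        with pytest.raises(ParameterError):
            peritumoral_mask(ball_mask, -1.0)


class TestExtractAll:
    def test_deterministic_and_schema_complete(self, rng):
        data = rng.normal(size=(8, 8, 8))
        mask = LesionMask(rng.random((8, 8, 8)) > 0.5, "GTVp", (1, 1, 1))
        a = extract_all(vol(data), mask)
        b = extract_all(vol(data), mask)
        assert tuple(a) == FEATURE_NAMES
        assert list(a.values()) == list(b.values())

    def test_intensity_shift_equivariance(self, rng):
        data = rng.normal(size=(8, 8, 8))
        mask = LesionMask(rng.random((8, 8, 8)) > 0.5, "GTVp", (1, 1, 1))
        a = extract_all(vol(data), mask)
        b = extract_all(vol(data + 100.0), mask)
        assert b["firstorder__mean"] == pytest.approx(a["firstorder__mean"] + 100.0)
        assert b["firstorder__variance"] == pytest.approx(a["firstorder__variance"])
        # fixed-bin-count discretization is shift invariant, so texture is too
        assert b["glcm__contrast"] == pytest.approx(a["glcm__contrast"])
        assert b["glrlm__short_run_emphasis"] == pytest.approx(a["glrlm__short_run_emphasis"])

    def test_rotation_invariance_of_direction_averaged_features(self, rng):
        data = rng.normal(size=(7, 7, 7))
        maskdata = rng.random((7, 7, 7)) > 0.4
        a = extract_all(vol(data), LesionMask(maskdata, "GTVp", (1, 1, 1)))
        rot = lambda x: np.rot90(x, k=1, axes=(0, 1))
        b = extract_all(vol(rot(data)), LesionMask(rot(maskdata), "GTVp", (1, 1, 1)))
        for name in FEATURE_NAMES:
            if name.startswith(("glcm__", "glrlm__", "glszm__", "gldm__")):
                assert b[name] == pytest.approx(a[name], abs=1e-8), name

    def test_texture_tracks_heterogeneity_dial(self):
        """GLCM contrast in the tumor core rises with the generator's texture knob.

        Uptake is held fixed so rim partial-volume texture (which scales with
        the tumor-to-background contrast) does not confound the dial, and the
        mask is eroded by one PET voxel to measure interior texture. Fixed bin
        width in SUV units — the standard PET discretization — keeps texture
        amplitude-sensitive (bin-count bins stretch with the range).
        """
        from scipy import ndimage
        from scipy.stats import spearmanr

        from petfuse.imaging import resample_to_grid
        from petfuse.synthetic import CohortSpec, generate_patient

        spec = CohortSpec(
            n_patients=40, seed=42, heterogeneity_range=(0.0, 2.5), uptake_range=(8.0, 8.0)
        )
        cfg = RadiomicsConfig(DiscretizationConfig("fixed_bin_width", bin_width=0.25))
        het, contrast = [], []
        for i in range(spec.n_patients):
            p = generate_patient(spec, i)
            pet_ct = resample_to_grid(p.pet, p.ct)
            core = ndimage.binary_erosion(p.gtvp.data, iterations=2)
            mask = LesionMask(core, "GTVp", p.gtvp.spacing, p.gtvp.origin)
            feats = extract_all(pet_ct, mask, cfg)
            het.append(p.truth["heterogeneity"])
            contrast.append(feats["glcm__contrast"])
        rho = spearmanr(het, contrast).statistic
        assert rho > 0.8
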