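"""Radiomic feature extraction: hand oracles, invariances, partition laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from habitatomics.features import (
    DIRECTIONS_13,
    discretize,
    extract_all,
    extract_features,
    first_order_features,
    glcm_features,
    glcm_matrix,
    glrlm_features,
    glszm_features,
    resample,
    shape_features,
)
from oracles import glcm_features_bruteforce


class TestResample:
    def test_isotropic_input_is_identity(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(size=(12, 12, 12))
        out = resample(vol, (1.0, 1.0, 1.0), (1.0, 1.0, 1.0))
        np.testing.assert_allclose(out, vol)

    def test_downsampled_shape_arithmetic(self):
        vol = np.zeros((10, 10, 10))
        out = resample(vol, (2.0, 2.0, 2.0), (1.0, 1.0, 1.0))
        assert out.shape == (20, 20, 20)

    def test_constant_volume_stays_constant(self):
        vol = np.full((8, 8, 8), 3.5)
        out = resample(vol, (1.0, 1.0, 2.5), (1.0, 1.0, 1.0))
        np.testing.assert_allclose(out, 3.5)

    def test_mask_stays_binary_under_nearest(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        out = resample(mask, (1.0, 1.0, 2.0), (1.0, 1.0, 1.0), order=0)
        assert out.dtype == bool
        assert set(np.unique(out)) <= {False, True}

    def test_missing_spacing_rejected(self):
        with pytest.raises(ValueError):
            resample(np.zeros((4, 4, 4)), (1.0, 0.0, 1.0))


class TestDiscretize:
    def test_extremes_map_to_first_and_last_level(self):
        x = np.array([0.0, 0.3, 1.0])
        lev = discretize(x, 25)
        assert lev[0] == 1 and lev[-1] == 25

    def test_uniform_values_fill_levels_evenly(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 100_000)
        lev = discretize(x, 25)
        freq = np.bincount(lev, minlength=26)[1:] / len(x)
        np.testing.assert_allclose(freq, 1 / 25, atol=0.005)

    def test_constant_region_single_level(self):
        lev = discretize(np.full(10, 2.0), 25)
        assert (lev == 1).all()

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30))
    def test_levels_always_in_range(self, vals):
        lev = discretize(np.array(vals), 25)
        assert lev.min() >= 1 and lev.max() <= 25


class TestFirstOrder:
    def test_hand_values(self):
        f = first_order_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert f["Mean"] == 2.5
        assert f["Variance"] == 1.25  # population convention
        assert f["Range"] == 3.0
        assert f["Energy"] == 30.0

    def test_constant_region_degenerate_but_defined(self):
        f = first_order_features(np.full(20, 5.0))
        assert f["Variance"] == 0.0
        assert f["Entropy"] == 0.0
        assert f["Uniformity"] == 1.0
        assert f["Skewness"] == 0.0

    def test_scaling_homogeneity(self):
        rng = np.random.default_rng(2)
        x = rng.normal(10, 2, 500)
        f1 = first_order_features(x)
        f3 = first_order_features(3.0 * x)
        assert np.isclose(f3["Mean"], 3 * f1["Mean"])
        assert np.isclose(f3["Variance"], 9 * f1["Variance"])

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            first_order_features(np.array([]))


class TestGLCM:
    def test_toy_grid_matches_pair_enumeration(self):
        disc = np.array([[[1], [1], [2]], [[1], [2], [2]], [[2], [2], [2]]])
        # offset (0,1,0): horizontal pairs within each row of the 3x3 slab
        P = glcm_matrix(disc, (0, 1, 0), 2)
        counts = P * 12  # 6 voxel pairs, symmetrized
        # pairs: one (1,1), two (1,2), three (2,2)
        np.testing.assert_allclose(
            counts, np.array([[2.0, 2.0], [2.0, 6.0]]), atol=1e-12
        )
        ours = glcm_features(disc, 2)
        oracle = glcm_features_bruteforce(disc, 2)
        for k, v in oracle.items():
            np.testing.assert_allclose(ours[k], v, atol=1e-12)

    def test_single_level_region_is_degenerate(self):
        disc = np.zeros((4, 4, 4), dtype=int)
        disc[1:3, 1:3, 1:3] = 1
        f = glcm_features(disc, 25)
        assert f["Contrast"] == 0.0
        assert f["Energy"] == 1.0
        assert f["JointEntropy"] == 0.0

    def test_gray_level_permutation_preserves_entropy(self):
        rng = np.random.default_rng(3)
        disc = np.zeros((5, 5, 5), dtype=int)
        disc[1:4, 1:4, 1:4] = rng.integers(1, 5, size=(3, 3, 3))
        perm = np.array([0, 3, 1, 4, 2])  # permutation of levels 1..4
        f1 = glcm_features(disc, 4)
        f2 = glcm_features(perm[disc], 4)
        np.testing.assert_allclose(f1["JointEntropy"], f2["JointEntropy"], atol=1e-12)

    def test_single_voxel_rejected(self):
        disc = np.zeros((3, 3, 3), dtype=int)
        disc[1, 1, 1] = 1
        with pytest.raises(ValueError):
            glcm_features(disc, 25)


class TestGLRLM:
    def test_constant_line_single_run(self):
        disc = np.zeros((4, 1, 1), dtype=int)
        disc[:, 0, 0] = 3
        f = glrlm_features(disc)
        # along the x axis: one run of length 4 -> RP = 1/4; other
        # directions have 4 runs of length 1 -> RP = 1
        per_dir_rp = [1 / 4] + [1.0] * 12
        np.testing.assert_allclose(f["RunPercentage"], np.mean(per_dir_rp))

    def test_checkerboard_axis_runs_all_length_one(self):
        from habitatomics.features import _runs_along

        x = np.indices((4, 4, 1)).sum(axis=0) % 2 + 1
        runs = _runs_along(x, (1, 0, 0))
        assert all(length == 1 for _, length in runs)
        assert len(runs) == 16  # SRE along that axis = 1


class TestGLSZM:
    def test_two_disjoint_blobs_two_zones(self):
        disc = np.zeros((8, 8, 1), dtype=int)
        disc[0:1, 0:5, 0] = 1  # 5-voxel zone at level 1
        disc[4:5, 0:3, 0] = 2  # 3-voxel zone at level 2
        f = glszm_features(disc)
        assert f["ZonePercentage"] == 2 / 8
        assert f["SmallAreaEmphasis"] == (1 / 25 + 1 / 9) / 2

    def test_diagonal_touching_merges_by_26_connectivity(self):
        disc = np.zeros((3, 3, 3), dtype=int)
        disc[0, 0, 0] = 1
        disc[1, 1, 1] = 1
        f = glszm_features(disc)
        assert f["LargeAreaEmphasis"] == 4.0  # one zone of size 2


class TestShape:
    def test_single_voxel(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        f = shape_features(mask, (1.0, 1.0, 1.0))
        assert f["Volume"] == 1.0
        assert f["SurfaceArea"] == 6.0

    def test_cube_hand_arithmetic(self):
        mask = np.zeros((14, 14, 14), bool)
        mask[2:12, 2:12, 2:12] = True
        f = shape_features(mask, (1.0, 1.0, 1.0))
        assert f["Volume"] == 1000.0
        assert f["SurfaceArea"] == 600.0
        np.testing.assert_allclose(
            f["Maximum3DDiameter"], 9 * np.sqrt(3.0), rtol=1e-12
        )

    def test_ball_rounder_than_slab(self):
        g = np.ogrid[:21, :21, :21]
        ball = sum((x - 10.0) ** 2 for x in g) <= 36
        slab = np.zeros((21, 21, 21), bool)
        slab[10, :, :] = True
        fb = shape_features(ball)
        fs = shape_features(slab)
        assert fb["Sphericity"] > fs["Sphericity"]
        assert 0 < fb["Sphericity"] <= 1.05  # discretization slack

    def test_anisotropic_spacing_volume(self):
        mask = np.ones((2, 2, 2), bool)
        f = shape_features(mask, (1.0, 1.0, 2.5))
        assert f["Volume"] == 8 * 2.5


class TestExtractAll:
    def _volume(self, seed=0):
        rng = np.random.default_rng(seed)
        img = rng.normal(50, 5, (16, 16, 16))
        mask = np.zeros((16, 16, 16), bool)
        mask[3:13, 3:13, 3:13] = True
        labels = np.zeros((16, 16, 16), dtype=int)
        labels[mask] = 1
        labels[8:13, 3:13, 3:13] = 2
        labels[~mask] = 0
        return img, labels, mask

    def test_subregions_partition_the_tumor(self):
        img, labels, mask = self._volume()
        table = extract_all(img, labels, mask).set_index("region")
        v_e = table.loc["VOIe", "shape_Volume"]
        v_1 = table.loc["VOI1", "shape_Volume"]
        v_2 = table.loc["VOI2", "shape_Volume"]
        assert v_1 + v_2 == v_e
        assert table.loc["VOIe", "n_voxels"] == mask.sum()

    def test_same_feature_bank_per_region(self):
        img, labels, mask = self._volume()
        table = extract_all(img, labels, mask)
        assert not table["excluded"].any()
        feature_cols = [
            c for c in table.columns
            if c not in ("patient_id", "region", "n_voxels", "excluded")
        ]
        assert table[feature_cols].notna().all().all()
        assert len(feature_cols) == len(set(feature_cols))

    def test_tiny_subregion_flagged_excluded(self):
        img, labels, mask = self._volume()
        labels[labels == 2] = 1
        labels[3, 3, 3] = 2  # single-voxel subregion
        table = extract_all(img, labels, mask).set_index("region")
        assert bool(table.loc["VOI2", "excluded"])
        assert not bool(table.loc["VOI1", "excluded"])

    def test_misaligned_grids_rejected(self):
        img, labels, mask = self._volume()
        with pytest.raises(ValueError):
            extract_all(img, labels[:-1], mask)

    def test_translation_invariance(self):
        """Shifting the tumor within the image changes no feature."""
        rng = np.random.default_rng(4)
        patch = rng.normal(40, 8, (6, 6, 6))
        out = {}
        for shift in ((2, 2, 2), (7, 5, 9)):
            img = np.zeros((16, 16, 16))
            mask = np.zeros((16, 16, 16), bool)
            sl = tuple(slice(s, s + 6) for s in shift)
            img[sl] = patch
            mask[sl] = True
            out[shift] = extract_features(img, mask)
        for k, v in out[(2, 2, 2)].items():
            np.testing.assert_allclose(out[(7, 5, 9)][k], v, atol=1e-10, err_msg=k)
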