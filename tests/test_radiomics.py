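import numpy as np
import pytest

import _oracles as orc
from conftest import make_roi
from nodal_petrad.images import ROIMask, SUVImage
from nodal_petrad.radiomics import (FAMILY_SIZES, DiscretizedROI, compute_glcm,
                                    compute_glrlm, compute_glszm, direction_set,
                                    discretize, extract_all, first_order_features,
                                    glcm_features, glrlm_features, glszm_features,
                                    ivh_features, shape_features)


def _disc(vol, roi):
    vol = np.asarray(vol, dtype=np.int64)
    roi = np.asarray(roi, dtype=bool)
    return DiscretizedROI(volume=np.where(roi, vol, 0), mask=roi,
                          bin_width=0.5, n_levels=int(vol[roi].max()))


class TestDiscretize:
    def test_printed_equation_hand_example(self, line_roi):
        image, mask = line_roi
        disc = discretize(image, mask, 0.5)
        assert disc.labels.tolist() == [1, 2, 2, 5]
        assert disc.n_levels == 5

    def test_constant_roi_single_level(self):
        image, mask = make_roi(np.full((3, 3, 3), 7.3))
        disc = discretize(image, mask)
        assert disc.n_levels == 1
        assert set(disc.labels) == {1}

    def test_high_values_relabelled_from_one(self):
        arr = np.zeros((2, 1, 1))
        arr[:, 0, 0] = [10.0, 10.4]
        image, mask = make_roi(arr)
        disc = discretize(image, mask)
        assert sorted(disc.labels.tolist()) == [1, 2]

    def test_errors(self):
        image, mask = make_roi(np.ones((2, 2, 2)))
        with pytest.raises(ValueError):
            discretize(image, mask, bin_width=0.0)
        empty = ROIMask(np.zeros((2, 2, 2), bool))
        with pytest.raises(ValueError):
            discretize(image, empty)
        neg, m2 = make_roi(-np.ones((2, 2, 2)))
        with pytest.raises(ValueError):
            discretize(neg, m2)

    def test_translation_covariance_of_texture(self):
        rng = np.random.default_rng(11)
        arr = rng.uniform(0.7, 6.0, size=(5, 5, 4))
        image, mask = make_roi(arr)
        shifted, _ = make_roi(arr + 3 * 0.5)
        f1 = extract_all(image, mask)
        f2 = extract_all(shifted, mask)
        unchanged = [k for k in f1 if k.split("_")[0] in ("glcm", "glrlm", "glszm")]
        unchanged += ["stats_entropy", "stats_uniformity"]
        for k in unchanged:
            assert f1[k] == pytest.approx(f2[k], abs=1e-10), k


class TestDirectionSet:
    def test_thirteen_unique_offsets(self):
        dirs = direction_set()
        assert len(dirs) == 13
        assert len(set(dirs)) == 13

    def test_no_offset_negates_another(self):
        dirs = set(direction_set())
        assert all(tuple(-c for c in d) not in dirs for d in dirs)

    def test_signed_closure_is_26_neighborhood(self):
        dirs = direction_set()
        closure = set(dirs) | {tuple(-c for c in d) for d in dirs}
        full = {(x, y, z) for x in (-1, 0, 1) for y in (-1, 0, 1)
                for z in (-1, 0, 1)} - {(0, 0, 0)}
        assert closure == full


class TestTextureMatrices:
    def test_glcm_two_adjacent_voxels(self):
        vol = np.zeros((2, 1, 1), dtype=int)
        vol[:, 0, 0] = [1, 2]
        mat = compute_glcm(_disc(vol, np.ones_like(vol, bool)))
        expected = np.array([[0.0, 0.5], [0.5, 0.0]])
        np.testing.assert_allclose(mat, expected)

    def test_glcm_constant_cube(self):
        disc = _disc(np.ones((2, 2, 2), int), np.ones((2, 2, 2), bool))
        np.testing.assert_allclose(compute_glcm(disc), [[1.0]])

    def test_glcm_isolated_voxels_error(self):
        roi = np.zeros((5, 5, 5), bool)
        roi[0, 0, 0] = roi[4, 4, 4] = True
        vol = np.where(roi, 1, 0)
        with pytest.raises(ValueError):
            compute_glcm(_disc(vol, roi))

    def test_glrlm_line_runs(self):
        # bins [1,1,2] along x: x-runs are (level 1, len 2), (level 2, len 1)
        vol = np.zeros((3, 1, 1), dtype=int)
        vol[:, 0, 0] = [1, 1, 2]
        roi = np.ones_like(vol, bool)
        mat = compute_glrlm(_disc(vol, roi))
        oracle = orc.glrlm_oracle(np.where(roi, vol, 0), roi, 2, mat.shape[1])
        np.testing.assert_allclose(mat, oracle)
        # the x-direction alone contributes one len-2 run of level 1
        assert mat[0, 1] == pytest.approx(1 / 13)

    def test_glrlm_single_voxel(self):
        mat = compute_glrlm(_disc(np.ones((1, 1, 1), int), np.ones((1, 1, 1), bool)))
        assert mat[0, 0] == pytest.approx(1.0)

    def test_glrlm_run_conservation(self, phantom):
        image, tumor, _ = phantom
        disc = discretize(image, tumor)
        mat = compute_glrlm(disc)
        r = np.arange(1, mat.shape[1] + 1)
        assert (mat * r).sum() == pytest.approx(tumor.n_voxels)

    def test_glszm_hand_zones(self):
        # one slice [[1,1],[2,1]]: the three 1s form a single 26-connected zone
        vol = np.array([[[1], [1]], [[2], [1]]])
        roi = np.ones_like(vol, bool)
        mat = compute_glszm(_disc(vol, roi))
        assert mat[0, 2] == 1   # level 1, size 3
        assert mat[1, 0] == 1   # level 2, size 1
        assert mat.sum() == 2

    def test_glszm_constant_single_zone(self):
        vol = np.ones((3, 2, 2), int)
        mat = compute_glszm(_disc(vol, np.ones_like(vol, bool)))
        assert mat[0, -1] == 1 and mat.sum() == 1

    def test_glszm_voxel_conservation(self, phantom):
        image, tumor, _ = phantom
        mat = compute_glszm(discretize(image, tumor))
        s = np.arange(1, mat.shape[1] + 1)
        assert (mat * s).sum() == tumor.n_voxels

    @pytest.mark.parametrize("seed", range(12))
    def test_matrices_match_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vol, roi, ng = orc.random_discretized_volume(rng)
        disc = _disc(vol, roi)
        np.testing.assert_allclose(compute_glcm(disc),
                                   orc.glcm_oracle(vol, roi, ng), atol=1e-12)
        ours = compute_glrlm(disc)
        np.testing.assert_allclose(ours, orc.glrlm_oracle(vol, roi, ng,
                                                          ours.shape[1]), atol=1e-12)
        ours = compute_glszm(disc)
        np.testing.assert_allclose(ours, orc.glszm_oracle(vol, roi, ng,
                                                          ours.shape[1]), atol=1e-12)

    def test_glcm_symmetry_on_phantom(self, phantom):
        image, tumor, _ = phantom
        mat = compute_glcm(discretize(image, tumor))
        np.testing.assert_allclose(mat, mat.T)
        assert mat.sum() == pytest.approx(1.0)


class TestFirstOrder:
    def test_hand_arithmetic(self):
        arr = np.zeros((4, 1, 1))
        arr[:, 0, 0] = [1, 2, 3, 4]
        image, mask = make_roi(arr)
        f = first_order_features(image, mask)
        assert f["stats_mean"] == pytest.approx(2.5)
        assert f["stats_range"] == pytest.approx(3.0)
        assert f["stats_rms"] == pytest.approx(np.sqrt(7.5))
        assert f["stats_median"] == pytest.approx(2.5)
        assert f["stats_energy"] == pytest.approx(30.0)

    def test_constant_roi_degenerate(self):
        image, mask = make_roi(np.full((3, 3, 3), 4.2))
        f = first_order_features(image, mask)
        assert f["stats_variance"] == pytest.approx(0.0, abs=1e-24)
        assert f["stats_uniformity"] == pytest.approx(1.0)
        assert f["stats_entropy"] == pytest.approx(0.0)
        assert f["stats_cov"] == pytest.approx(0.0, abs=1e-15)

    def test_symmetric_values_zero_skew(self):
        arr = np.zeros((5, 1, 1))
        arr[:, 0, 0] = [1, 2, 3, 4, 5]
        image, mask = make_roi(arr)
        assert first_order_features(image, mask)["stats_skewness"] == pytest.approx(0, abs=1e-12)

    def test_suv_peak_neighborhood_mean(self):
        arr = np.ones((3, 3, 3))
        arr[1, 1, 1] = 10.0
        image, mask = make_roi(arr)
        f = first_order_features(image, mask)
        # 3x3x3 neighborhood of the hottest voxel covers the full ROI
        assert f["stats_suv_peak"] == pytest.approx((26 + 10) / 27)
        assert f["stats_max"] == 10.0

    def test_mean_max_equal_direct_reductions(self, phantom):
        image, tumor, _ = phantom
        f = first_order_features(image, tumor)
        vals = image.values[tumor.indicator]
        assert f["stats_mean"] == pytest.approx(vals.mean())
        assert f["stats_max"] == pytest.approx(vals.max())


class TestShape:
    def test_single_voxel_volume_at_dev_spacing(self):
        mask = ROIMask(np.ones((1, 1, 1), bool), spacing=(4.0728, 4.0728, 3.0))
        f = shape_features(mask)
        assert f["shape_volume_cc"] * 1000 == pytest.approx(4.0728 * 4.0728 * 3, rel=1e-9)

    def test_digital_ball_sphericity(self):
        r = 8.5
        g = np.ogrid[:20, :20, :20]
        ball = sum((a - 9.5) ** 2 for a in g) <= r * r
        f = shape_features(ROIMask(ball, spacing=(1, 1, 1)))
        assert f["shape_sphericity"] == pytest.approx(1.0, abs=0.08)
        assert f["shape_max_3d_diameter"] == pytest.approx(2 * r, abs=1.8)
        assert f["shape_elongation"] == pytest.approx(1.0, abs=0.05)
        assert f["shape_flatness"] == pytest.approx(1.0, abs=0.05)

    def test_cube_diagonal_within_one_voxel(self):
        a = 5
        m = np.zeros((8, 8, 8), bool)
        m[1:1 + a, 1:1 + a, 1:1 + a] = True
        f = shape_features(ROIMask(m, spacing=(1, 1, 1)))
        assert abs(f["shape_max_3d_diameter"] - a * np.sqrt(3)) <= 1.0
        assert f["shape_max_2d_diameter_z"] == pytest.approx(a * np.sqrt(2), abs=1.0)
        assert f["shape_volume_cc"] == pytest.approx(a ** 3 / 1000)

    def test_translation_invariance(self):
        m1 = np.zeros((10, 10, 10), bool)
        m1[1:4, 2:6, 3:5] = True
        m2 = np.roll(m1, (3, 1, 2), axis=(0, 1, 2))
        f1 = shape_features(ROIMask(m1))
        f2 = shape_features(ROIMask(m2))
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-9), k


class TestIVH:
    def test_threshold_at_minimum_gives_full_volume(self, phantom):
        image, tumor, _ = phantom
        f = ivh_features(image, tumor)
        # V at 0% of the range is not reported, but V10..V90 are <= 1 and
        # the histogram is non-increasing in the threshold
        vx = [f[f"ivh_v{p}"] for p in range(10, 100, 10)]
        assert all(0 <= v <= 1 for v in vx)
        assert all(a >= b - 1e-12 for a, b in zip(vx, vx[1:]))

    def test_constant_roi_auc_is_one(self):
        image, mask = make_roi(np.full((3, 3, 3), 2.0))
        f = ivh_features(image, mask)
        assert f["ivh_auc"] == 1.0
        assert f["ivh_v50"] == 1.0

    def test_ix_monotone(self, phantom):
        image, tumor, _ = phantom
        f = ivh_features(image, tumor)
        ix = [f[f"ivh_i{p}"] for p in range(10, 100, 10)]
        assert all(a >= b - 1e-12 for a, b in zip(ix, ix[1:]))
        assert f["ivh_i10"] >= f["ivh_i90"]

    def test_absolute_thresholds_hand_case(self):
        arr = np.zeros((4, 1, 1))
        arr[:, 0, 0] = [0.5, 1.5, 2.5, 3.5]
        image, mask = make_roi(arr)   # 1 mm voxels -> 0.001 cc each
        f = ivh_features(image, mask)
        assert f["ivh_vf_suv1"] == pytest.approx(0.75)
        assert f["ivh_vf_suv3"] == pytest.approx(0.25)
        assert f["ivh_vol_cc_suv2"] == pytest.approx(2 * 0.001)
        # AUC = (mean - min)/range = (2.0 - 0.5)/3.0
        assert f["ivh_auc"] == pytest.approx(0.5)


class TestTextureFeatures:
    def test_glrlm_sre_hand_value(self):
        mat = np.array([[0.0, 1.0], [1.0, 0.0]])  # (g1,len2):1 and (g2,len1):1
        f = glrlm_features(mat, n_voxels=3)
        assert f["glrlm_sre"] == pytest.approx((1 / 4 + 1) / 2)
        assert f["glrlm_rp"] == pytest.approx(2 / 3)

    def test_all_runs_length_one_sre_is_one(self):
        mat = np.array([[3.0], [2.0]])
        f = glrlm_features(mat, n_voxels=5)
        assert f["glrlm_sre"] == 1.0
        assert f["glrlm_lre"] == 1.0

    def test_glcm_degenerate_single_level(self):
        f = glcm_features(np.array([[1.0]]))
        assert f["glcm_entropy"] == 0.0
        assert f["glcm_max_probability"] == 1.0
        assert f["glcm_correlation"] == 0.0
        assert f["glcm_imc1"] == 0.0
        assert f["glcm_imc2"] == 0.0

    def test_glszm_rosters(self):
        f = glszm_features(np.array([[1.0, 1.0]]), n_voxels=3)
        assert len(f) == 11
        assert f["glszm_zp"] == pytest.approx(2 / 3)


class TestExtractAll:
    def test_feature_count_and_families(self, phantom):
        image, tumor, _ = phantom
        feats = extract_all(image, tumor)
        assert len(feats) == 118
        for fam, k in FAMILY_SIZES.items():
            assert sum(1 for name in feats if name.startswith(fam + "_")) == k
        assert all(np.isfinite(v) for v in feats.values())

    def test_model_features_present_under_canonical_names(self, phantom):
        image, tumor, _ = phantom
        feats = extract_all(image, tumor)
        for name in ("glrlm_sre", "glrlm_gln", "glrlm_srhge", "glcm_entropy",
                     "shape_volume_cc", "shape_surface_to_volume_ratio",
                     "stats_uniformity", "stats_suv_peak"):
            assert name in feats

    def test_deterministic(self, phantom):
        image, tumor, _ = phantom
        f1 = extract_all(image, tumor)
        f2 = extract_all(image, tumor)
        assert f1 == f2
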