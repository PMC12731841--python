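import numpy as np
import pytest

import histotex as hx
from histotex.texture_features import GLCM_ANGLES

from conftest import quantized_from_levels
from oracles import glcm_oracle, gldm_oracle, glszm_oracle, ngtdm_oracle


def random_masked_case(rng, size=8, ng=4):
    levels = rng.integers(1, ng + 1, (size, size)).astype(np.int32)
    mask = rng.random((size, size)) > 0.2
    if not mask.any():
        mask[0, 0] = True
    levels[~mask] = 0
    q = hx.QuantizedImage(levels=levels, ng=ng,
                          bin_edges=np.linspace(0, 1, ng + 1),
                          pixel_spacing=5.0)
    return q, hx.ROIMask(mask)


class TestGLCM:
    def test_two_column_pairs(self):
        q, roi = quantized_from_levels([[1, 2], [1, 2]], ng=2)
        m = hx.compute_glcm(q, roi, angles=((0, 1),), symmetric=True)
        assert m.counts[0, 0, 1] == 2 and m.counts[0, 1, 0] == 2
        assert m.probabilities[0, 0, 1] == pytest.approx(0.5)
        assert m.probabilities[0, 1, 0] == pytest.approx(0.5)

    def test_constant_single_cell(self, constant_image):
        q, roi = constant_image
        m = hx.compute_glcm(q, roi)
        for k in range(4):
            assert m.probabilities[k, 0, 0] == pytest.approx(1.0)

    def test_symmetric_equals_transpose(self, rng):
        q, roi = random_masked_case(rng)
        m = hx.compute_glcm(q, roi, symmetric=True)
        np.testing.assert_array_equal(m.counts, m.counts.transpose(0, 2, 1))

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(10):
            q, roi = random_masked_case(rng, ng=int(rng.integers(2, 7)))
            m = hx.compute_glcm(q, roi)
            expected = glcm_oracle(q.levels, roi.mask, q.ng, 1,
                                   GLCM_ANGLES, True)
            np.testing.assert_array_equal(m.counts, expected)

    def test_empty_angles_raises(self, random_quantized):
        q, roi = random_quantized
        with pytest.raises(ValueError):
            hx.compute_glcm(q, roi, angles=())


class TestGLCMFeatures:
    def test_constant_image_limits(self, constant_image):
        q, roi = constant_image
        fv = hx.glcm_features(hx.compute_glcm(q, roi))
        assert fv["GLCM Contrast"] == 0.0
        assert fv["GLCM Joint Energy"] == 1.0
        assert fv["GLCM Difference Entropy"] == 0.0

    def test_checkerboard_contrast_by_angle(self, checkerboard):
        q, roi = checkerboard
        axial = hx.glcm_features(hx.compute_glcm(q, roi, angles=((0, 1),)))
        diag = hx.glcm_features(hx.compute_glcm(q, roi, angles=((-1, 1),)))
        allang = hx.glcm_features(hx.compute_glcm(q, roi))
        assert axial["GLCM Contrast"] == pytest.approx(1.0)
        assert diag["GLCM Contrast"] == pytest.approx(0.0)
        assert allang["GLCM Contrast"] == pytest.approx(0.5)

    def test_idn_bounds(self, rng):
        """IDN lies in (0, 1]; it attains 1 iff all mass is diagonal."""
        for _ in range(10):
            q, roi = random_masked_case(rng)
            fv = hx.glcm_features(hx.compute_glcm(q, roi))
            assert 0.0 < fv["GLCM Inverse Difference Normalized"] <= 1.0
        q, roi = quantized_from_levels(np.ones((4, 4), int), ng=1)
        fv = hx.glcm_features(hx.compute_glcm(q, roi))
        assert fv["GLCM Inverse Difference Normalized"] == pytest.approx(1.0)

    def test_against_skimage_counts(self, rng):
        """Cross-check raw counts with an established GLCM implementation."""
        from skimage.feature import graycomatrix

        levels = rng.integers(1, 5, (12, 12)).astype(np.uint8)
        q, roi = quantized_from_levels(levels, ng=4)
        m = hx.compute_glcm(q, roi, angles=((0, 1),), symmetric=True)
        sk = graycomatrix(levels - 1, [1], [0], levels=4, symmetric=True)
        np.testing.assert_array_equal(m.counts[0], sk[:, :, 0, 0])


class TestGLSZM:
    def test_constant_single_zone(self, constant_image):
        q, roi = constant_image
        m = hx.compute_glszm(q, roi)
        assert m.nz == 1
        assert m.counts[0, 15] == 1

    def test_three_zones_by_hand(self):
        q, roi = quantized_from_levels([[1, 1, 2], [1, 2, 2], [3, 3, 3]], ng=3)
        m = hx.compute_glszm(q, roi)
        assert m.nz == 3
        assert np.all(m.counts.sum(axis=0)[2] == 3)  # all zones size 3
        fv = hx.glszm_features(m)
        assert fv["GLSZM Size Zone Non-Uniformity Normalized"] == pytest.approx(1.0)

    def test_checkerboard_two_zones(self, checkerboard):
        q, roi = checkerboard
        m = hx.compute_glszm(q, roi)
        assert m.nz == 2
        assert m.counts[0, 7] == 1 and m.counts[1, 7] == 1
        fv = hx.glszm_features(m)
        assert fv["GLSZM Small Area Emphasis"] == pytest.approx(1.0 / 64)

    def test_single_zone_small_area_emphasis(self, constant_image):
        q, roi = constant_image
        fv = hx.glszm_features(hx.compute_glszm(q, roi))
        assert fv["GLSZM Small Area Emphasis"] == pytest.approx(1.0 / 256)

    def test_pixel_conservation_and_oracle(self, rng):
        for _ in range(10):
            q, roi = random_masked_case(rng, ng=int(rng.integers(2, 7)))
            m = hx.compute_glszm(q, roi)
            sizes = np.arange(1, m.counts.shape[1] + 1)
            assert (m.counts * sizes).sum() == roi.n_pixels
            expected = glszm_oracle(q.levels, roi.mask, q.ng)
            np.testing.assert_array_equal(m.counts, expected)


class TestGLDM:
    def test_constant_3x3_dependences(self):
        q, roi = quantized_from_levels(np.ones((3, 3), int), ng=1)
        m = hx.compute_gldm(q, roi, alpha=0, distance=1)
        assert m.counts[0, 3] == 4   # corners
        assert m.counts[0, 5] == 4   # edges
        assert m.counts[0, 8] == 1   # center

    def test_single_pixel_roi(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        levels = np.zeros((3, 3), np.int32)
        levels[1, 1] = 2
        q = hx.QuantizedImage(levels, ng=3, bin_edges=np.linspace(0, 1, 4),
                              pixel_spacing=1.0)
        m = hx.compute_gldm(q, hx.ROIMask(mask))
        assert m.counts[1, 0] == 1 and m.counts.sum() == 1

    def test_dependence_variance_moment_oracle(self):
        """Constant 3x3: dependence multiset {3,3,3,3,5,5,5,5,8}."""
        deps = np.array([3, 3, 3, 3, 5, 5, 5, 5, 8], dtype=float)
        expected = ((deps - deps.mean()) ** 2).mean()
        q, roi = quantized_from_levels(np.ones((3, 3), int), ng=1)
        fv = hx.gldm_features(hx.compute_gldm(q, roi))
        assert fv["GLDM Dependence Variance"] == pytest.approx(expected)

    def test_constant_gray_level_emphases(self, constant_image):
        q, roi = constant_image
        fv = hx.gldm_features(hx.compute_gldm(q, roi))
        assert fv["GLDM Low Gray-Level Emphasis"] == pytest.approx(1.0)
        assert fv["GLDM High Gray-Level Emphasis"] == pytest.approx(1.0)

    def test_point_mass_zero_variance(self):
        q, roi = quantized_from_levels([[2, 2], [2, 2]], ng=2)
        fv = hx.gldm_features(hx.compute_gldm(q, roi))
        assert fv["GLDM Dependence Variance"] == pytest.approx(0.0)

    def test_count_conservation_and_oracle(self, rng):
        for _ in range(10):
            q, roi = random_masked_case(rng, size=6, ng=int(rng.integers(2, 6)))
            alpha = int(rng.integers(0, 2))
            m = hx.compute_gldm(q, roi, alpha=alpha)
            assert m.counts.sum() == roi.n_pixels
            expected = gldm_oracle(q.levels, roi.mask, q.ng, alpha, 1)
            np.testing.assert_array_equal(m.counts, expected)

    def test_negative_alpha_raises(self, random_quantized):
        q, roi = random_quantized
        with pytest.raises(ValueError):
            hx.compute_gldm(q, roi, alpha=-1)


class TestNGTDM:
    def test_constant_zero_differences(self, constant_image):
        q, roi = constant_image
        m = hx.compute_ngtdm(q, roi)
        assert np.all(m.s == 0.0)

    def test_center_spike_hand_values(self):
        lv = np.ones((3, 3), int)
        lv[1, 1] = 2
        q, roi = quantized_from_levels(lv, ng=2)
        m = hx.compute_ngtdm(q, roi)
        assert m.s[1] == pytest.approx(1.0)
        assert m.s[0] == pytest.approx(4 * (1 / 3) + 4 * (1 / 5))
        fv = hx.ngtdm_features(m)
        assert fv["NGTDM Coarseness"] == pytest.approx(135 / 271)
        assert fv["NGTDM Contrast"] == pytest.approx(376 / 10935)
        assert fv["NGTDM Busyness"] == pytest.approx(271 / 180)
        assert fv["NGTDM Complexity"] == pytest.approx(542 / 1215)
        assert fv["NGTDM Strength"] == pytest.approx(30 / 47)

    def test_two_level_equal_probabilities(self):
        lv = np.array([[1, 1], [2, 2]])
        q, roi = quantized_from_levels(lv, ng=2)
        m = hx.compute_ngtdm(q, roi)
        np.testing.assert_allclose(m.p, [0.5, 0.5])

    def test_constant_feature_limits(self, constant_image):
        q, roi = constant_image
        fv = hx.ngtdm_features(hx.compute_ngtdm(q, roi))
        assert fv["NGTDM Contrast"] == 0.0
        assert fv["NGTDM Busyness"] == 0.0
        assert fv["NGTDM Coarseness"] == pytest.approx(1e6)

    def test_matches_neighborhood_oracle(self, rng):
        for _ in range(10):
            q, roi = random_masked_case(rng, size=5, ng=int(rng.integers(2, 6)))
            m = hx.compute_ngtdm(q, roi)
            s, n, p = ngtdm_oracle(q.levels, roi.mask, q.ng, 1)
            np.testing.assert_allclose(m.s, s, atol=1e-12)
            np.testing.assert_array_equal(m.n, n)


class TestExtractAll:
    def test_census_and_determinism(self, rng):
        q, roi = random_masked_case(rng)
        fv1 = hx.extract_all(q, roi)
        fv2 = hx.extract_all(q, roi)
        assert len(fv1) == 59
        assert fv1.family_counts() == {"GLCM": 24, "GLSZM": 16,
                                       "GLDM": 14, "NGTDM": 5}
        assert fv1.names == hx.ALL_FEATURE_NAMES
        assert fv1.values == fv2.values

    def test_all_values_finite(self, rng):
        for _ in range(5):
            q, roi = random_masked_case(rng, ng=int(rng.integers(2, 9)))
            fv = hx.extract_all(q, roi)
            assert all(np.isfinite(v) for v in fv.values.values())

    def test_rotation_invariance(self, rng):
        """Angle-averaged features are unchanged by a 90-degree rotation."""
        levels = rng.integers(1, 6, (10, 10)).astype(np.int32)
        q, roi = quantized_from_levels(levels, ng=5)
        q_rot, roi_rot = quantized_from_levels(np.rot90(levels), ng=5)
        fv = hx.extract_all(q, roi)
        fv_rot = hx.extract_all(q_rot, roi_rot)
        for name in fv.names:
            assert fv[name] == pytest.approx(fv_rot[name], rel=1e-10), name
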