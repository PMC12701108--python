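import numpy as np
import pytest
from skimage.draw import disk as sk_disk

from dcecad.core import ContractError
from dcecad.features import (
    FeatureConfig,
    contrast_features,
    dilate_mask,
    extract_feature_vector,
    feature_names,
    glcm_features,
    ring_mask,
)
from dcecad.fp_rules import region_props


class TestDilateMask:
    def test_single_pixel_becomes_cross(self):
        m = np.zeros((9, 9), bool)
        m[4, 4] = True
        out = dilate_mask(m, 1)
        assert out.sum() == 5
        assert out[4, 4] and out[3, 4] and out[5, 4] and out[4, 3] and out[4, 5]

    def test_extensive(self, rng):
        m = rng.random((20, 20)) > 0.7
        assert np.all(m <= dilate_mask(m, 2))

    def test_radius_zero_is_identity(self, rng):
        m = rng.random((10, 10)) > 0.5
        assert np.array_equal(dilate_mask(m, 0), m)

    def test_negative_radius_rejected(self):
        with pytest.raises(ContractError):
            dilate_mask(np.zeros((4, 4), bool), -1)


class TestRingMask:
    def test_annulus_geometry(self):
        m = np.zeros((40, 40), bool)
        rr, cc = sk_disk((20, 20), 10)
        m[rr, cc] = True
        ring = ring_mask(m, 4)
        assert not (ring & m).any()
        assert ring.sum() > 0
        rows, cols = np.nonzero(ring)
        radius = np.sqrt((rows - 20.0) ** 2 + (cols - 20.0) ** 2)
        assert radius.max() <= 14.5 and radius.min() >= 9.0

    def test_empty_mask_gives_empty_ring(self):
        assert not ring_mask(np.zeros((8, 8), bool)).any()

    def test_nonempty_mask_gives_nonempty_ring(self):
        m = np.zeros((10, 10), bool)
        m[5, 5] = True
        assert ring_mask(m).sum() > 0


class TestGlcmFeatures:
    def test_stripe_image_matches_hand_enumeration(self):
        """[[0,1],[0,1]] at d=1, 0 degrees: p(0,1)=p(1,0)=1/2 exactly."""
        img = np.array([[0.0, 1.0], [0.0, 1.0]])
        g = glcm_features(img, np.ones((2, 2), bool), levels=2,
                          distances=(1,), angles=(0,))
        assert g["contrast_d1"] == pytest.approx(1.0)
        assert g["energy_d1"] == pytest.approx(0.5)
        assert g["homogeneity_d1"] == pytest.approx(0.5)
        assert g["entropy_d1"] == pytest.approx(1.0)
        assert g["idm_d1"] == pytest.approx(0.5)
        assert g["correlation_d1"] == pytest.approx(-1.0)

    def test_constant_roi_degenerate_statistics(self):
        img = np.full((6, 6), 0.4)
        g = glcm_features(img, np.ones((6, 6), bool))
        for d in (1, 2):
            assert g[f"contrast_d{d}"] == 0.0
            assert g[f"energy_d{d}"] == 1.0
            assert g[f"homogeneity_d{d}"] == 1.0
            assert g[f"entropy_d{d}"] == 0.0

    def test_invariant_under_90_degree_rotation(self, rng):
        img = rng.random((24, 24))
        mask = np.zeros((24, 24), bool)
        mask[6:18, 8:20] = rng.random((12, 12)) > 0.2
        g1 = glcm_features(img, mask)
        g2 = glcm_features(np.rot90(img), np.rot90(mask))
        for key, val in g1.items():
            assert g2[key] == pytest.approx(val, abs=1e-10)

    def test_pairs_outside_mask_do_not_leak(self):
        # two identical ROIs, one embedded in a bright surround: same stats
        img1 = np.zeros((12, 12))
        img2 = np.ones((12, 12))
        patch = np.linspace(0, 1, 16).reshape(4, 4)
        img1[4:8, 4:8] = patch
        img2[4:8, 4:8] = patch
        mask = np.zeros((12, 12), bool)
        mask[4:8, 4:8] = True
        g1 = glcm_features(img1, mask, distances=(1,))
        g2 = glcm_features(img2, mask, distances=(1,))
        for key in g1:
            assert g1[key] == pytest.approx(g2[key], abs=1e-12)

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ContractError):
            glcm_features(rng.random((8, 8)), np.zeros((8, 8), bool))


class TestContrastFeatures:
    def _regions(self, inside_vals, ring_vals):
        n = len(inside_vals) + len(ring_vals)
        img = np.zeros((1, n))
        img[0, : len(inside_vals)] = inside_vals
        img[0, len(inside_vals):] = ring_vals
        mask = np.zeros((1, n), bool)
        ring = np.zeros((1, n), bool)
        mask[0, : len(inside_vals)] = True
        ring[0, len(inside_vals):] = True
        return img, mask, ring

    def test_con_ratio(self):
        img, mask, ring = self._regions([149.0, 151.0], [49.0, 51.0])
        out = contrast_features(img, mask, ring)
        assert out["con"] == pytest.approx(0.5)    # (150-50)/(150+50)

    def test_equal_means_give_zero(self):
        img, mask, ring = self._regions([5.0, 7.0], [4.0, 8.0])
        out = contrast_features(img, mask, ring)
        assert out["con"] == pytest.approx(0.0)
        assert out["c"] == pytest.approx(0.0)

    def test_c_ratio(self):
        s = np.sqrt(2.0)
        img, mask, ring = self._regions([10 - s, 10 + s], [6 - s, 6 + s])
        out = contrast_features(img, mask, ring)
        assert out["c"] == pytest.approx(16.0 / 4.0)

    def test_zero_sum_means_rejected(self):
        img, mask, ring = self._regions([0.0], [0.0])
        with pytest.raises(ZeroDivisionError):
            contrast_features(img, mask, ring)

    def test_overlapping_regions_rejected(self, rng):
        img = rng.random((4, 4))
        m = np.ones((4, 4), bool)
        with pytest.raises(ContractError):
            contrast_features(img, m, m)


class TestExtractFeatureVector:
    def _roi(self, rng, shape=(40, 40)):
        frame = np.zeros(shape, bool)
        rr, cc = sk_disk((20, 20), 6)
        frame[rr, cc] = True
        return region_props(frame)[0]

    def test_default_vector_has_14_entries(self, rng):
        vec = extract_feature_vector(rng.random((40, 40)), self._roi(rng))
        assert len(vec) == 14
        assert vec.names == feature_names()

    def test_extras_extend_to_16(self, rng):
        cfg = FeatureConfig(include_extras=True)
        vec = extract_feature_vector(rng.random((40, 40)), self._roi(rng), cfg)
        assert len(vec) == 16
        assert vec.names[-2:] == ["roi_mean", "roi_sd"]

    def test_deterministic(self, rng):
        img = rng.random((40, 40))
        roi = self._roi(rng)
        v1 = extract_feature_vector(img, roi)
        v2 = extract_feature_vector(img.copy(), roi)
        assert np.array_equal(v1.values, v2.values)

    def test_shift_invariance_set(self, rng):
        """Adding a constant to the image changes CON only: the GLCM
        statistics quantise over the ROI's own range and C is a ratio of
        squared differences to variances."""
        img = 0.2 + 0.5 * rng.random((40, 40))
        roi = self._roi(rng)
        v1 = extract_feature_vector(img, roi)
        v2 = extract_feature_vector(img + 0.2, roi)
        d1 = v1.as_dict()
        d2 = v2.as_dict()
        for name in feature_names():
            if name == "con":
                assert d2[name] != pytest.approx(d1[name], abs=1e-6)
            else:
                assert d2[name] == pytest.approx(d1[name], abs=1e-9)
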