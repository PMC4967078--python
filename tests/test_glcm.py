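"""GLCM construction and the 18 texture features.

The worked numerical values in this file were hand-evaluated on tiny
matrices or computed with the brute-force pair-enumeration oracle in
``glcm_oracle.py``.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from glcm_oracle import naive_features, naive_glcm, naive_quantize
from radstab.glcm import (
    GLCM_FEATURES,
    GLCMMatrix,
    GLCMSpec,
    NoValidPairsError,
    aggregate_directions,
    compute_glcm,
    extract_all,
    glcm_feature,
    glcm_offsets,
    quantize_roi,
)
from radstab.grid import ROIMask, VolumeGrid


class TestOffsets:
    def test_thirteen_canonical_offsets(self):
        offs = glcm_offsets()
        assert len(offs) == 13
        assert {(1, 0, 0), (0, 1, 0), (0, 0, 1)} <= set(offs)
        assert (-1, 0, 0) not in offs
        # one representative per antipodal pair, none zero
        assert all(o != (0, 0, 0) for o in offs)
        assert all(tuple(-c for c in o) not in offs for o in offs)
        # together with their negatives they tile the 26-neighbourhood
        full = set(offs) | {tuple(-c for c in o) for o in offs}
        assert len(full) == 26


class TestQuantize:
    def _vol(self, values):
        arr = np.asarray(values, dtype=float).reshape(1, 1, -1)
        return VolumeGrid(arr), ROIMask(np.ones(arr.shape, bool))

    def test_extremes_map_to_extreme_levels(self):
        vol, mask = self._vol([0, 99])
        labels = quantize_roi(vol, mask, 2)
        assert list(labels[0, 0]) == [1, 2]

    def test_bin_edge_arithmetic(self):
        vol, mask = self._vol([0, 49.9, 50, 100])
        labels = quantize_roi(vol, mask, 2)
        assert list(labels[0, 0]) == [1, 1, 2, 2]

    def test_constant_roi_maps_to_level_one(self):
        vol, mask = self._vol([7.0] * 5)
        labels = quantize_roi(vol, mask, 25)
        assert set(labels[mask.data]) == {1}

    def test_matches_naive_quantizer(self, rng):
        for _ in range(20):
            vals = rng.normal(0, 100, size=int(rng.integers(2, 50)))
            levels = int(rng.integers(2, 33))
            vol, mask = self._vol(vals)
            got = quantize_roi(vol, mask, levels)[mask.data]
            assert list(got) == naive_quantize(list(vals), levels)


class TestComputeGLCM:
    def _labels_2x2(self):
        labels = np.array([[[1, 2], [1, 2]]], dtype=np.int32)
        mask = ROIMask(np.ones((1, 2, 2), bool))
        return labels, mask

    def test_symmetrized_two_pair_example(self):
        labels, mask = self._labels_2x2()
        m = compute_glcm(labels, mask, (0, 0, 1), levels=2, symmetrize=True)
        want = np.array([[0, 0.5], [0.5, 0]])
        np.testing.assert_allclose(m.P, want, atol=1e-12)

    def test_asymmetric_two_pair_example(self):
        labels, mask = self._labels_2x2()
        m = compute_glcm(labels, mask, (0, 0, 1), levels=2, symmetrize=False)
        want = np.array([[0, 1.0], [0, 0]])
        np.testing.assert_allclose(m.P, want, atol=1e-12)

    def test_constant_labels(self):
        labels = np.ones((2, 2, 2), dtype=np.int32)
        mask = ROIMask(np.ones((2, 2, 2), bool))
        m = compute_glcm(labels, mask, (1, 0, 0), levels=3, symmetrize=True)
        assert m.P[0, 0] == pytest.approx(1.0)

    def test_offset_exceeding_roi_raises(self):
        labels = np.ones((1, 1, 2), dtype=np.int32)
        data = np.zeros((1, 1, 2), bool)
        data[0, 0, 0] = True
        with pytest.raises(NoValidPairsError):
            compute_glcm(labels, ROIMask(data), (0, 0, 1), levels=2, symmetrize=True)


# hand evaluation of every base feature on P(1,2) = P(2,1) = 0.5
_WORKED_2X2 = {
    "Mean": 1.5,
    "Variance": 0.25,
    "Energy": 0.5,
    "Entropy": math.log(2),
    "Contrast": 1.0,
    "Correlation": -1.0,
    "Dissimilarity": 1.0,
    "Homogeneity": 0.5,
    "Diff average": 1.0,
    "Diff variance": 0.0,
    "Diff entropy": 0.0,
    "Sum average": 3.0,
    "Sum variance": 0.0,
    "Sum entropy": 0.0,
    "Angular 2nd moment": 0.5,
}


class TestFeatureValues:
    def test_worked_2x2_matrix(self):
        m = GLCMMatrix(np.array([[0, 0.5], [0.5, 0]]))
        for name, want in _WORKED_2X2.items():
            assert glcm_feature(m, name) == pytest.approx(want, abs=1e-9), name

    def test_single_cell_distribution_policies(self):
        m = GLCMMatrix(np.array([[1.0, 0], [0, 0]]))
        assert glcm_feature(m, "Contrast") == 0.0
        assert glcm_feature(m, "Homogeneity") == 1.0
        assert glcm_feature(m, "Energy") == 1.0
        assert glcm_feature(m, "Entropy") == 0.0
        assert glcm_feature(m, "Correlation") == 0.0  # zero-sigma policy
        assert glcm_feature(m, "Information correlation A") == 0.0

    def test_uniform_matrix_closed_forms(self):
        L = 5
        m = GLCMMatrix(np.full((L, L), 1.0 / L**2))
        assert glcm_feature(m, "Energy") == pytest.approx(1 / L**2)
        assert glcm_feature(m, "Entropy") == pytest.approx(2 * math.log(L))
        # independence with uniform marginals: Hxy2 == Hxy, so ICB == 0
        assert glcm_feature(m, "Information correlation B") == pytest.approx(0, abs=1e-12)

    def test_unknown_feature_raises(self):
        m = GLCMMatrix(np.array([[1.0]]))
        with pytest.raises(ValueError):
            glcm_feature(m, "Fractal dimension")

    def test_mcc_of_independent_distribution_is_zero(self, rng):
        px = rng.dirichlet(np.ones(6))
        py = rng.dirichlet(np.ones(6))
        m = GLCMMatrix(np.outer(px, py), symmetrized=False)
        assert abs(glcm_feature(m, "Maximal correlation coefficient")) < 1e-8

    def test_sqrt_variants(self):
        m = GLCMMatrix(np.array([[0.4, 0.1], [0.1, 0.4]]))
        icb = glcm_feature(m, "Information correlation B")
        assert glcm_feature(m, "Information correlation B", icb_sqrt=True) == (
            pytest.approx(math.sqrt(icb))
        )
        mcc = glcm_feature(m, "Maximal correlation coefficient")
        assert glcm_feature(
            m, "Maximal correlation coefficient", mcc_sqrt=True
        ) == pytest.approx(math.sqrt(max(mcc, 0.0)))


class TestMatrixInvariants:
    def _random_matrix(self, rng, symmetrize):
        L = int(rng.integers(2, 9))
        labels = rng.integers(1, L + 1, size=(4, 4, 4)).astype(np.int32)
        mask = ROIMask(rng.random((4, 4, 4)) < 0.8)
        if not mask.data.any():
            mask.data[0, 0, 0] = mask.data[0, 0, 1] = True
        off = glcm_offsets()[int(rng.integers(13))]
        try:
            return compute_glcm(labels, mask, off, L, symmetrize)
        except NoValidPairsError:
            return None

    def test_normalisation_and_symmetry(self, rng):
        for _ in range(50):
            m = self._random_matrix(rng, symmetrize=True)
            if m is None:
                continue
            assert m.P.sum() == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_array_equal(m.P, m.P.T)
            np.testing.assert_allclose(m.Px, m.Py, atol=1e-12)
            assert m.mu_x == pytest.approx(m.mu_y, abs=1e-12)
            assert m.Hx == pytest.approx(m.Hy, abs=1e-12)
            assert m.Pxpy.sum() == pytest.approx(1.0, abs=1e-9)
            assert m.Pxmy.sum() == pytest.approx(1.0, abs=1e-9)

    def test_feature_ranges(self, rng):
        for _ in range(50):
            m = self._random_matrix(rng, symmetrize=bool(rng.integers(2)))
            if m is None:
                continue
            L = m.levels
            assert 0 < glcm_feature(m, "Energy") <= 1 + 1e-12
            assert 0 < glcm_feature(m, "Homogeneity") <= 1 + 1e-12
            assert glcm_feature(m, "Contrast") >= 0
            assert glcm_feature(m, "Diff variance") >= -1e-12
            assert glcm_feature(m, "Sum variance") >= -1e-12
            assert 2 - 1e-9 <= glcm_feature(m, "Sum average") <= 2 * L + 1e-9
            if m.sigma_x * m.sigma_y > 0:
                assert -1 - 1e-9 <= glcm_feature(m, "Correlation") <= 1 + 1e-9

    def test_affine_intensity_invariance(self, rng):
        """Quantization depends on intensities only through min/max, so any
        increasing affine map leaves every GLCM feature unchanged."""
        vol = VolumeGrid(rng.normal(0, 50, size=(5, 5, 5)))
        mask = ROIMask(rng.random((5, 5, 5)) < 0.8)
        mask.data[0, 0, :2] = True
        spec = GLCMSpec(levels=8)
        vol2 = VolumeGrid(2.5 * vol.values + 300.0)
        for off in [(0, 0, 1), (1, -1, 0)]:
            a = compute_glcm(quantize_roi(vol, mask, 8), mask, off, 8, True)
            b = compute_glcm(quantize_roi(vol2, mask, 8), mask, off, 8, True)
            np.testing.assert_allclose(a.P, b.P, atol=1e-12)


class TestAggregation:
    def test_constant_values(self):
        assert aggregate_directions([3.0] * 13) == (3.0, 0.0)

    def test_grid_values(self):
        values = [k / 13 for k in range(1, 14)]
        mean, rng_ = aggregate_directions(values)
        assert mean == pytest.approx(7 / 13)
        assert rng_ == pytest.approx(12 / 13)

    def test_single_value(self):
        assert aggregate_directions([2.5]) == (2.5, 0.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            aggregate_directions([])


class TestExtractAll:
    def _roi(self, rng, side=5):
        vol = VolumeGrid(rng.normal(0, 50, size=(side, side, side)))
        mask = ROIMask(rng.random((side, side, side)) < 0.9)
        return vol, mask

    def test_battery_sizes(self, rng):
        vol, mask = self._roi(rng)
        df = extract_all(vol, mask, [GLCMSpec(25), GLCMSpec(32)])
        assert len(df) == 80
        df25 = extract_all(vol, mask, [GLCMSpec(25)])
        assert len(df25) == 44
        fams = set(df["family"])
        assert fams == {
            "Histogram",
            "GLCM(25) mean", "GLCM(25) range",
            "GLCM(32) mean", "GLCM(32) range",
        }

    def test_empty_mask_raises(self, rng):
        vol, _ = self._roi(rng)
        with pytest.raises(ValueError):
            extract_all(vol, ROIMask(np.zeros(vol.shape, bool)))

    def test_energy_equals_angular_second_moment(self, rng):
        vol, mask = self._roi(rng)
        df = extract_all(vol, mask, [GLCMSpec(25)])
        piv = df[df.family != "Histogram"].pivot_table(
            index="family", columns="feature", values="value"
        )
        np.testing.assert_allclose(
            piv["Energy"], piv["Angular 2nd moment"], atol=1e-12
        )


class TestOracleEquivalence:
    def test_random_small_rois_match_brute_force(self, rng):
        """Spot equivalence on a handful of random ROIs (the full 100-ROI
        sweep lives in the acceptance suite)."""
        checked = 0
        while checked < 10:
            shape = tuple(int(rng.integers(2, 7)) for _ in range(3))
            vol = VolumeGrid(np.round(rng.normal(0, 60, size=shape)))
            mask = ROIMask(rng.random(shape) < 0.7)
            if mask.count < 4:
                continue
            levels = int(rng.integers(2, 9))
            labels = quantize_roi(vol, mask, levels)
            off = glcm_offsets()[int(rng.integers(13))]
            want_P = naive_glcm(labels, mask.data, off, levels, symmetrize=True)
            if want_P is None:
                continue
            m = compute_glcm(labels, mask, off, levels, symmetrize=True)
            np.testing.assert_allclose(m.P, np.array(want_P), atol=1e-12)
            want = naive_features(want_P)
            for name in GLCM_FEATURES:
                assert glcm_feature(m, name) == pytest.approx(
                    want[name], abs=1e-9
                ), name
            checked += 1


def test_cross_check_against_skimage_2d(rng):
    """Independent cross-check: single-slice ROI against scikit-image's 2D
    GLCM for the in-plane offsets (features that are invariant to the 0- vs
    1-based level convention)."""
    from skimage.feature import graycomatrix, graycoprops

    img = rng.integers(0, 8, size=(12, 12)).astype(np.uint8)
    vol = VolumeGrid(img[None].astype(float))
    mask = ROIMask(np.ones((1, 12, 12), bool))
    labels = (img[None] + 1).astype(np.int32)  # identity quantization
    for off, (dist, angle) in [((0, 0, 1), (1, 0.0)), ((0, 1, 0), (1, np.pi / 2))]:
        ours = compute_glcm(labels, mask, off, 8, symmetrize=True)
        theirs = graycomatrix(img, [dist], [angle], levels=8, symmetric=True, normed=True)
        np.testing.assert_allclose(ours.P, theirs[:, :, 0, 0], atol=1e-12)
        for name, prop in [
            ("Contrast", "contrast"),
            ("Dissimilarity", "dissimilarity"),
            ("Homogeneity", "homogeneity"),
            ("Correlation", "correlation"),
            ("Energy", "ASM"),
        ]:
            want = graycoprops(theirs, prop)[0, 0]
            assert glcm_feature(ours, name) == pytest.approx(want, abs=1e-9), name
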