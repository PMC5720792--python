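import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tumortex as tx
from tumortex.cooccur import (
    CooccurrenceMatrix,
    acm_feature_block,
    compute_acm,
    compute_glcm,
    compute_rlm,
    cooccurrence_stats19,
    rlm_features,
    sobel_gradients,
    _rlm_stats,
)
from tumortex.errors import DegenerateROIError
from tumortex.image_io import quantize_roi

from _oracles import (
    acm_bruteforce,
    glcm_bruteforce,
    rlm_bruteforce,
    sobel_bruteforce,
)

from tumortex.cooccur import STAT_NAMES

IDX = {n: i for i, n in enumerate(STAT_NAMES)}


def _random_masked_roi(seed, shape=(8, 8), p_mask=0.85):
    rng = np.random.default_rng(seed)
    mask = rng.random(shape) < p_mask
    mask[shape[0] // 2, shape[1] // 2] = True
    return tx.SliceROI(rng.uniform(0, 100, shape), mask)


class TestGLCM:
    def test_constant_roi_is_delta_matrix(self, rois):
        q = quantize_roi(rois["constant8"], N=16)
        M = compute_glcm(q, d=2)
        assert M.P[0, 0] == pytest.approx(1.0)
        assert M.P.sum() == pytest.approx(1.0)
        assert M.P.shape == (16, 16)

    def test_checkerboard_at_distance_two_stays_on_diagonal(self, rois):
        # period-1 checkerboard: displacement 2 always lands on the same level
        q = quantize_roi(rois["checker"], N=16)
        M = compute_glcm(q, d=2)
        off_diag = M.P - np.diag(np.diag(M.P))
        assert np.abs(off_diag).max() == 0.0

    @pytest.mark.parametrize("name", ["rampxy", "quant4", "lmask", "checker"])
    def test_matches_bruteforce_enumeration(self, rois, name):
        q = quantize_roi(rois[name], N=16)
        M = compute_glcm(q, d=2)
        expected = glcm_bruteforce(q.levels, q.mask, 16, 2, (0, 45, 90, 135))
        np.testing.assert_array_equal(M.P, expected)

    def test_matches_bruteforce_on_random_masked_rois(self):
        for seed in range(5):
            roi = _random_masked_roi(seed)
            q = quantize_roi(roi, N=8)
            M = compute_glcm(q, d=2)
            expected = glcm_bruteforce(q.levels, q.mask, 8, 2, (0, 45, 90, 135))
            np.testing.assert_array_equal(M.P, expected)

    def test_symmetric_normalized_nonnegative(self, random_roi):
        q = quantize_roi(random_roi, N=16)
        M = compute_glcm(q, d=2)
        assert np.allclose(M.P, M.P.T)
        assert M.P.min() >= 0
        assert M.P.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rotation_invariance_of_statistics(self, random_roi):
        """The four-direction average makes GLCM statistics invariant to a
        90-degree rotation of a square fully-masked ROI."""
        q = quantize_roi(random_roi, N=16)
        rot = tx.SliceROI(np.rot90(random_roi.intensities).copy(),
                          np.rot90(random_roi.mask).copy())
        qr = quantize_roi(rot, N=16)
        s1 = cooccurrence_stats19(compute_glcm(q, d=2))
        s2 = cooccurrence_stats19(compute_glcm(qr, d=2))
        np.testing.assert_allclose(s1, s2, atol=1e-9)

    def test_isolated_pixels_raise_degenerate(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[0, 0] = mask[7, 7] = True  # no pair at distance 2 in any direction
        roi = tx.SliceROI(np.ones((8, 8)), mask)
        with pytest.raises(DegenerateROIError):
            compute_glcm(quantize_roi(roi, N=4), d=2)


class TestCooccurrenceStats19:
    def _delta(self, n=4, k=0):
        P = np.zeros((n, n))
        P[k, k] = 1.0
        return CooccurrenceMatrix(P=P, N=n, kind="glcm")

    def test_delta_matrix_closed_forms(self):
        s = cooccurrence_stats19(self._delta(), q=8.0, r=2.0)
        assert s[IDX["energy"]] == pytest.approx(1.0)
        assert s[IDX["contrast"]] == pytest.approx(0.0)
        assert s[IDX["entropy"]] == pytest.approx(0.0)
        assert s[IDX["renyi_entropy"]] == pytest.approx(0.0)
        # printed Tsallis form: (1/(1-2)) * sum(P^2) = -1 for a delta matrix
        assert s[IDX["tsallis_entropy"]] == pytest.approx(-1.0)

    def test_uniform_two_by_two_renyi_is_two_bits(self):
        P = np.full((2, 2), 0.25)
        s = cooccurrence_stats19(CooccurrenceMatrix(P, 2, "glcm"), q=8.0, r=2.0)
        # (1/(1-8)) * log2(4 * 0.25^8) = 2 bits
        assert s[IDX["renyi_entropy"]] == pytest.approx(2.0)

    def test_renyi_order_one_limit_is_shannon(self, random_roi):
        q = quantize_roi(random_roi, N=16)
        M = compute_glcm(q, d=2)
        s = cooccurrence_stats19(M, q=1.0 + 1e-6, r=2.0)
        assert s[IDX["renyi_entropy"]] == pytest.approx(
            s[IDX["entropy"]], abs=1e-3
        )

    def test_inertia_duplicates_contrast(self, random_roi):
        q = quantize_roi(random_roi, N=16)
        s = cooccurrence_stats19(compute_glcm(q, d=2))
        assert s[IDX["inertia"]] == pytest.approx(s[IDX["contrast"]])

    def test_conventional_tsallis_flag(self):
        P = np.full((2, 2), 0.25)
        s = cooccurrence_stats19(
            CooccurrenceMatrix(P, 2, "glcm"), r=2.0, tsallis_conventional=True
        )
        assert s[IDX["tsallis_entropy"]] == pytest.approx(1.0 - 0.25)

    def test_all_finite_on_degenerate_marginals(self):
        s = cooccurrence_stats19(self._delta(n=16, k=5))
        assert np.isfinite(s).all()


class TestRLM:
    def test_constant_roi_single_runs_per_row(self, rois):
        roi4 = tx.SliceROI(np.full((4, 4), 7.0), np.ones((4, 4), dtype=bool))
        q = quantize_roi(roi4, N=16)
        R = compute_rlm(q, 0).R
        assert R[0, 3] == 4  # four rows, each one run of length 4
        assert R.sum() == 4

    def test_checkerboard_axis_runs_length_one(self, rois):
        # along rows/columns the two levels alternate every pixel; along the
        # diagonals a checkerboard is constant, so only 0/90 are length-1
        q = quantize_roi(rois["checker"], N=16)
        for d in (0, 90):
            R = compute_rlm(q, d).R
            assert R[:, 1:].sum() == 0

    def test_run_percentage_on_constant_rows(self):
        roi4 = tx.SliceROI(np.full((4, 4), 7.0), np.ones((4, 4), dtype=bool))
        q = quantize_roi(roi4, N=16)
        stats = _rlm_stats(compute_rlm(q, 0).R)
        assert stats[4] == pytest.approx(4 / 16)  # RP = runs / pixels

    def test_checkerboard_sre_is_one_along_alternating_axes(self, rois):
        q = quantize_roi(rois["checker"], N=16)
        for d in (0, 90):
            assert _rlm_stats(compute_rlm(q, d).R)[0] == pytest.approx(1.0)
        assert rlm_features(q).shape == (11,)

    @pytest.mark.parametrize("direction", [0, 45, 90, 135])
    def test_masked_runs_match_bruteforce(self, rois, direction):
        q = quantize_roi(rois["lmask"], N=4)
        R = compute_rlm(q, direction).R
        expected = rlm_bruteforce(q.levels, q.mask, direction)
        got = {
            (lev + 1, ln + 1): int(R[lev, ln])
            for lev, ln in zip(*np.nonzero(R))
        }
        assert got == expected

    def test_pixel_accounting_invariant(self, random_roi):
        """Every traversed in-mask pixel is accounted once per direction."""
        q = quantize_roi(random_roi, N=8)
        ln = np.arange(1, max(q.levels.shape) + 1)
        for d in (0, 45, 90, 135):
            R = compute_rlm(q, d).R
            assert (R @ ln).sum() == q.mask.sum()

    def test_rotation_invariance_of_features(self, random_roi):
        q = quantize_roi(random_roi, N=8)
        rot = tx.SliceROI(np.rot90(random_roi.intensities).copy(),
                          np.rot90(random_roi.mask).copy())
        qr = quantize_roi(rot, N=8)
        np.testing.assert_allclose(rlm_features(q), rlm_features(qr), atol=1e-9)


class TestSobel:
    def test_ramp_has_uniform_zero_angle(self, rois):
        f = sobel_gradients(rois["rampx"])
        assert np.allclose(f.angle[f.valid], 0.0)
        mags = f.magnitude[f.valid]
        assert np.allclose(mags, mags[0]) and mags[0] > 0

    def test_constant_roi_zero_magnitude(self, rois):
        f = sobel_gradients(rois["constant8"])
        assert np.allclose(f.magnitude[f.valid], 0.0)
        assert np.allclose(f.angle[f.valid], 0.0)  # lands in bin 1

    def test_matches_bruteforce_convolution(self):
        roi = _random_masked_roi(3, shape=(5, 5), p_mask=1.0)
        f = sobel_gradients(roi)
        gx, gy, valid = sobel_bruteforce(roi.intensities, roi.mask)
        np.testing.assert_array_equal(f.valid, valid)
        ang = np.degrees(np.arctan2(gy, gx)) % 360
        mag = np.hypot(gx, gy)
        np.testing.assert_allclose(f.angle[valid], ang[valid], atol=1e-12)
        np.testing.assert_allclose(f.magnitude[valid], mag[valid], atol=1e-12)

    def test_no_interior_raises(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[0, :] = True
        with pytest.raises(DegenerateROIError):
            sobel_gradients(tx.SliceROI(np.ones((5, 5)), mask))


class TestACM:
    def test_ramp_gives_delta_matrix(self, rois):
        f = sobel_gradients(rois["rampx"])
        M = compute_acm(f, l=1, n_theta=8)
        assert M.P[0, 0] == pytest.approx(1.0)
        assert M.P.shape == (8, 8)

    def test_uniform_magnitude_makes_acm2_equal_acm1(self, rois):
        f = sobel_gradients(rois["rampx"])
        M1 = compute_acm(f, weighted=False)
        M2 = compute_acm(f, weighted=True)
        np.testing.assert_allclose(M1.P, M2.P, atol=1e-12)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_composite_matches_bruteforce(self, rois, weighted):
        f = sobel_gradients(rois["rampxy"])
        M = compute_acm(f, l=1, n_theta=8, weighted=weighted)
        expected = acm_bruteforce(
            f.angle, f.magnitude, f.valid, 1, 8, weighted, (0, 45, 90, 135)
        )
        np.testing.assert_allclose(M.P, expected, atol=1e-12)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_random_roi_matches_bruteforce(self, weighted):
        roi = _random_masked_roi(9, shape=(9, 9), p_mask=0.9)
        f = sobel_gradients(roi)
        M = compute_acm(f, l=1, n_theta=8, weighted=weighted)
        expected = acm_bruteforce(
            f.angle, f.magnitude, f.valid, 1, 8, weighted, (0, 45, 90, 135)
        )
        np.testing.assert_allclose(M.P, expected, atol=1e-12)

    def test_rotation_equivariance(self, random_roi):
        """Rotating the ROI by 90 degrees shifts every gradient by exactly
        two 45-degree bins: the ACM of the rotated ROI equals the original
        ACM with rows and columns cyclically relabeled."""
        f = sobel_gradients(random_roi)
        rot = tx.SliceROI(np.rot90(random_roi.intensities).copy(),
                          np.rot90(random_roi.mask).copy())
        fr = sobel_gradients(rot)
        for weighted in (False, True):
            M = compute_acm(f, weighted=weighted).P
            Mr = compute_acm(fr, weighted=weighted).P
            perm = (np.arange(8) + 2) % 8  # rotated bin b came from bin b+2
            np.testing.assert_allclose(Mr, M[np.ix_(perm, perm)], atol=1e-9)

    def test_relabeling_robust_stats_rotation_invariant(self, random_roi):
        """Statistics that ignore bin labels (energy, entropies) are fully
        invariant to 90-degree rotation even though label-dependent ones
        (e.g. sum average) legitimately change."""
        rot = tx.SliceROI(np.rot90(random_roi.intensities).copy(),
                          np.rot90(random_roi.mask).copy())
        b1 = acm_feature_block(random_roi)
        b2 = acm_feature_block(rot)
        for base in (0, 19):  # ACM1 block then ACM2 block
            for stat in ("energy", "entropy", "renyi_entropy", "tsallis_entropy"):
                assert b1[base + IDX[stat]] == pytest.approx(
                    b2[base + IDX[stat]], abs=1e-9
                )

    def test_block_shape_and_ramp_values(self, rois):
        block = acm_feature_block(rois["rampx"])
        assert block.shape == (38,)
        assert block[IDX["energy"]] == pytest.approx(1.0)  # A1
        assert block[IDX["entropy"]] == pytest.approx(0.0)  # A9


@settings(max_examples=20)
@given(st.integers(0, 2**31 - 1))
def test_cooccurrence_matrices_are_probability_matrices(seed):
    """Any GLCM/ACM on a random masked ROI is symmetric, nonnegative, and
    sums to one."""
    roi = _random_masked_roi(seed, shape=(7, 7), p_mask=0.95)
    q = quantize_roi(roi, N=8)
    try:
        G = compute_glcm(q, d=2)
        f = sobel_gradients(roi)
        A = compute_acm(f)
    except DegenerateROIError:
        return
    for M in (G, A):
        assert M.P.min() >= 0
        assert abs(M.P.sum() - 1.0) < 1e-9
        np.testing.assert_allclose(M.P, M.P.T, atol=1e-12)
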