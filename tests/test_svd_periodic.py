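import numpy as np
import pytest

from fecgkit import (InsufficientBeatsError, beats_to_signal,
                     build_beat_matrix, rank_truncate, singular_spectrum,
                     svd_estimate)
from fecgkit.simulate import synth_ecg


def periodic_signal(period=100, n_periods=8):
    beat = np.exp(-0.5 * ((np.arange(period) - 30) / 4.0) ** 2)
    x = np.tile(beat, n_periods)
    peaks = np.arange(30, len(x), period)
    return x, peaks


class TestBuildBeatMatrix:
    def test_periodic_rows_identical_rank_one(self):
        x, peaks = periodic_signal()
        bm = build_beat_matrix(x, peaks)
        assert bm.n == 100
        for row in bm.A[1:]:
            np.testing.assert_allclose(row, bm.A[0], atol=1e-12)
        assert np.linalg.matrix_rank(bm.A, tol=1e-8) == 1

    def test_hand_traced_segmentation(self):
        x = np.arange(400, dtype=float)
        bm = build_beat_matrix(x, [100, 190, 300])
        # median RR = 100 -> offset 30; segments [70,160) and [160,270)
        assert bm.m == 2
        assert bm.seg_bounds == [(70, 160), (160, 270)]
        assert bm.n == 100

    def test_too_few_peaks(self):
        with pytest.raises(InsufficientBeatsError):
            build_beat_matrix(np.zeros(400), [100, 200])

    def test_unordered_peaks(self):
        with pytest.raises(ValueError):
            build_beat_matrix(np.zeros(400), [100, 90, 200])


class TestSingularSpectrum:
    def test_identity(self):
        ss = singular_spectrum(np.eye(3))
        np.testing.assert_allclose(ss.values, [1, 1, 1])
        np.testing.assert_allclose(ss.diff_spectrum, [0, 0])

    def test_diag(self):
        ss = singular_spectrum(np.diag([3.0, 1.0]))
        np.testing.assert_allclose(ss.values, [3, 1])
        np.testing.assert_allclose(ss.diff_spectrum, [2])

    def test_rank_one_plus_noise_peaks_first(self, rng):
        A = np.outer(np.ones(6), rng.standard_normal(40))
        A += 0.01 * rng.standard_normal(A.shape)
        ss = singular_spectrum(A)
        assert int(np.argmax(ss.diff_spectrum)) == 0


class TestRankTruncate:
    def test_rank_one_exact(self, rng):
        A = np.outer(rng.standard_normal(5), rng.standard_normal(30))
        np.testing.assert_allclose(rank_truncate(A, 1), A, atol=1e-10)

    def test_full_rank_identity(self, rng):
        A = rng.standard_normal((4, 9))
        np.testing.assert_allclose(rank_truncate(A, 4), A, atol=1e-10)

    def test_rank_bound_exact(self, rng):
        A = rng.standard_normal((6, 8))
        assert np.linalg.matrix_rank(rank_truncate(A, 2), tol=1e-8) <= 2

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_eckart_young_identity(self, rng, k):
        # truncation error must equal the sum of squared discarded singulars
        A = rng.standard_normal((6, 8))
        s = np.linalg.svd(A, compute_uv=False)
        err = np.linalg.norm(A - rank_truncate(A, k), "fro") ** 2
        assert err == pytest.approx(float(np.sum(s[k:] ** 2)), abs=1e-8)

    def test_k_out_of_range(self, rng):
        with pytest.raises(ValueError):
            rank_truncate(rng.standard_normal((3, 5)), 4)


class TestBeatsToSignal:
    def test_lossless_on_periodic(self):
        x, peaks = periodic_signal()
        bm = build_beat_matrix(x, peaks)
        rec = beats_to_signal(bm.A, bm)
        a, b = bm.seg_bounds[0][0], bm.seg_bounds[-1][1]
        np.testing.assert_allclose(rec[a:b], x[a:b], atol=1e-9)
        np.testing.assert_allclose(rec[:a], 0.0)
        np.testing.assert_allclose(rec[b:], 0.0)

    def test_locality(self):
        x, peaks = periodic_signal()
        bm = build_beat_matrix(x, peaks)
        A2 = bm.A.copy()
        A2[2] += 1.0
        rec0 = beats_to_signal(bm.A, bm)
        rec2 = beats_to_signal(A2, bm)
        a, b = bm.seg_bounds[2]
        changed = np.nonzero(rec2 != rec0)[0]
        assert changed.size and changed.min() >= a and changed.max() < b

    def test_shape_mismatch(self):
        x, peaks = periodic_signal()
        bm = build_beat_matrix(x, peaks)
        with pytest.raises(ValueError):
            beats_to_signal(bm.A[:, :-1], bm)


class TestSvdEstimate:
    def test_denoises_periodic_signal(self, rng):
        x, peaks = periodic_signal(n_periods=20)
        noise = 0.05 * rng.standard_normal(len(x))
        est = svd_estimate(x + noise, peaks, k=2)
        mask = est != 0
        rmse = np.sqrt(np.mean((est[mask] - x[mask]) ** 2))
        assert rmse < np.std(noise)

    def test_clean_fetal_high_fidelity(self, clean_fetal):
        x, r, _ = clean_fetal
        est = svd_estimate(x, r, k=2, fs=1000.0)
        mask = est != 0
        assert np.corrcoef(est[mask], x[mask])[0, 1] >= 0.99

    def test_zero_signal(self):
        est = svd_estimate(np.zeros(500), [50, 150, 250, 350], k=1)
        np.testing.assert_allclose(est, 0.0)
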