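import numpy as np
import pytest
from scipy import signal as sig

from fecgkit import (DegenerateInputError, ECGRecord, FastICAConfig,
                     amari_error, center_whiten, fastica_overrelaxed,
                     separate)


def three_sources(N=20000):
    rng = np.random.default_rng(42)
    t = np.arange(N) / 1000.0
    S = np.vstack([np.sin(2 * np.pi * 7 * t),
                   sig.sawtooth(2 * np.pi * 5 * t),
                   rng.uniform(-1, 1, N)])
    return (S - S.mean(1, keepdims=True)) / S.std(1, keepdims=True)


def best_match_corr(true_sources, est_sources):
    k = true_sources.shape[0]
    corr = np.corrcoef(np.vstack([true_sources, est_sources]))[:k, k:]
    return np.abs(corr).max(axis=1)


class TestWhitening:
    def test_identity_covariance(self, rng):
        X = rng.standard_normal((3, 5000)) * [[1.0], [5.0], [0.2]]
        Z, W, mean = center_whiten(X)
        np.testing.assert_allclose(Z.mean(axis=1), 0.0, atol=1e-10)
        cov = Z @ Z.T / (Z.shape[1] - 1)
        np.testing.assert_allclose(cov, np.eye(3), atol=1e-8)

    def test_already_white_is_fixed_point(self, rng):
        Z0, _, _ = center_whiten(rng.standard_normal((2, 4000)))
        Z, W, _ = center_whiten(Z0)
        # whitening of already-white data is at most a sign/permutation
        np.testing.assert_allclose(np.abs(np.linalg.det(W)), 1.0, atol=1e-6)
        cov = Z @ Z.T / (Z.shape[1] - 1)
        np.testing.assert_allclose(cov, np.eye(2), atol=1e-8)

    def test_mixed_uniform_sources(self, rng):
        S = rng.uniform(-1, 1, (2, 10000))
        A = np.array([[1.0, 0.5], [0.3, 2.0]])
        Z, _, _ = center_whiten(A @ S)
        cov = Z @ Z.T / (Z.shape[1] - 1)
        assert np.abs(cov - np.eye(2)).max() < 0.05

    def test_rank_deficient_errors(self, rng):
        x = rng.standard_normal(1000)
        with pytest.raises(DegenerateInputError):
            center_whiten(np.vstack([x, 2 * x, x - 0.5 * x]))


class TestFastICA:
    def test_already_separated(self, rng):
        S = np.vstack([rng.uniform(-1, 1, 20000),
                       rng.laplace(size=20000)])
        Z, _, _ = center_whiten(S)
        res = fastica_overrelaxed(Z, FastICAConfig(seed=0))
        assert res.converged
        assert (best_match_corr(Z, res.sources) > 0.999).all()

    def test_three_source_recovery(self):
        S = three_sources()
        A = np.random.default_rng(7).uniform(-1, 1, (3, 3))
        Z, W, _ = center_whiten(A @ S)
        res = fastica_overrelaxed(Z, FastICAConfig(seed=1))
        assert (best_match_corr(S, res.sources) >= 0.95).all()
        assert amari_error(res.unmixing @ W @ A) < 0.1

    def test_sources_stay_white(self):
        S = three_sources()
        A = np.random.default_rng(9).uniform(-1, 1, (3, 3))
        Z, _, _ = center_whiten(A @ S)
        res = fastica_overrelaxed(Z, FastICAConfig(seed=3))
        cov = res.sources @ res.sources.T / (S.shape[1] - 1)
        np.testing.assert_allclose(cov, np.eye(3), atol=1e-6)

    def test_overrelaxation_same_fixed_point(self):
        S = three_sources()
        A = np.random.default_rng(11).uniform(-1, 1, (3, 3))
        Z, _, _ = center_whiten(A @ S)
        r1 = fastica_overrelaxed(Z, FastICAConfig(overrelax_lambda=1.0, seed=5))
        r2 = fastica_overrelaxed(Z, FastICAConfig(overrelax_lambda=1.5, seed=5))
        assert r1.converged and r2.converged
        assert (best_match_corr(r1.sources, r2.sources) >= 0.999).all()

    def test_bitwise_deterministic(self):
        S = three_sources(5000)
        A = np.random.default_rng(2).uniform(-1, 1, (3, 3))
        Z, _, _ = center_whiten(A @ S)
        r1 = fastica_overrelaxed(Z, FastICAConfig(seed=4))
        r2 = fastica_overrelaxed(Z, FastICAConfig(seed=4))
        assert np.array_equal(r1.sources, r2.sources)
        assert np.array_equal(r1.unmixing, r2.unmixing)

    def test_channel_permutation_gives_same_sources(self):
        S = three_sources()
        A = np.random.default_rng(3).uniform(-1, 1, (3, 3))
        X = A @ S
        P = np.eye(3)[[2, 0, 1]]
        out = []
        for data in (X, P @ X):
            Z, _, _ = center_whiten(data)
            out.append(fastica_overrelaxed(Z, FastICAConfig(seed=6)).sources)
        assert (best_match_corr(out[0], out[1]) > 0.99).all()

    def test_not_whitened_rejected(self, rng):
        with pytest.raises(ValueError, match="not whitened"):
            fastica_overrelaxed(5.0 * rng.standard_normal((2, 3000)))

    def test_nonconvergence_warns_not_raises(self, rng):
        Z, _, _ = center_whiten(rng.standard_normal((3, 3000)))
        with pytest.warns(RuntimeWarning):
            res = fastica_overrelaxed(Z, FastICAConfig(max_iter=1, tol=1e-12,
                                                       seed=0))
        assert not res.converged

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FastICAConfig(overrelax_lambda=0.0)
        with pytest.raises(ValueError):
            FastICAConfig(contrast="nope")


class TestSeparate:
    def test_single_channel_rejected(self):
        rec = ECGRecord(np.zeros((1, 100)) + np.arange(100), fs=100.0)
        with pytest.raises(ValueError):
            separate(rec)

    def test_finds_both_rhythms(self, abdominal_record):
        from fecgkit import PreprocessConfig
        from fecgkit.pipeline import classify_components
        res = separate(abdominal_record.record, FastICAConfig(seed=0),
                       preprocess_cfg=PreprocessConfig(artifact_k=None))
        labels = classify_components(res.sources, abdominal_record.record.fs)
        assert "maternal" in labels and "fetal" in labels

    def test_deterministic(self, abdominal_record):
        a = separate(abdominal_record.record, FastICAConfig(seed=1))
        b = separate(abdominal_record.record, FastICAConfig(seed=1))
        assert np.array_equal(a.sources, b.sources)
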