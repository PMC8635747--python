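"""Canonical correlation analysis against an independent eigenproblem oracle.

The oracle solves det(Rxy Ryy^-1 Ryx - lambda Rxx) = 0 directly with
scipy.linalg.eig — a different algebraic route than the SVD used by the
implementation — and squares of canonical correlations must agree to 1e-8.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

from ecogeo.cca import eigen_proportions, fit_cca, standardize, wilks_tests
from ecogeo.synthetic import planted_cca_sample


def oracle_canonical_correlations(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Brute-force generalized eigenproblem solution for the squared
    canonical correlations."""
    n = X.shape[0]
    Z = np.hstack([X, Y])
    R = np.corrcoef(Z, rowvar=False)
    p = X.shape[1]
    Rxx, Ryy = R[:p, :p], R[p:, p:]
    Rxy = R[:p, p:]
    lhs = Rxy @ np.linalg.inv(Ryy) @ Rxy.T
    vals = linalg.eig(lhs, Rxx)[0].real
    vals = np.clip(vals, 0.0, 1.0)
    return np.sqrt(np.sort(vals)[::-1][: min(p, R.shape[0] - p)])


def _std(arr):
    return standardize(pd.DataFrame(np.asarray(arr, dtype=float)))


class TestStandardize:
    def test_three_point_column(self):
        out = standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert np.allclose(out["x"], [-1.0, 0.0, 1.0])

    def test_idempotent_and_moments(self, rng):
        block = pd.DataFrame(rng.normal(5, 3, size=(50, 4)))
        out = standardize(block)
        assert np.allclose(out.mean(), 0.0, atol=1e-12)
        assert np.allclose(out.std(ddof=1), 1.0, atol=1e-12)
        assert np.allclose(standardize(out), out, atol=1e-12)

    def test_zero_variance_hard_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            standardize(pd.DataFrame({"x": [2.0, 2.0, 2.0]}))


class TestFit:
    def test_identical_single_columns_give_r_one(self, rng):
        x = rng.normal(size=50)
        res = fit_cca(_std(x[:, None]), _std(x[:, None].copy()))
        assert res.correlations[0] == pytest.approx(1.0, abs=1e-10)

    def test_independent_blocks_near_zero(self):
        rng = np.random.default_rng(99)
        res = fit_cca(
            _std(rng.normal(size=(10_000, 2))), _std(rng.normal(size=(10_000, 2)))
        )
        assert res.correlations.max() < 0.05

    def test_fixed_integer_table_matches_oracle(self):
        X = np.array(
            [[1, 2], [2, 1], [3, 5], [4, 3], [5, 8], [6, 5], [7, 9], [8, 7]],
            dtype=float,
        )
        Y = np.array(
            [[2, 1], [1, 3], [4, 2], [3, 6], [7, 4], [5, 9], [9, 6], [8, 10]],
            dtype=float,
        )
        res = fit_cca(_std(X), _std(Y))
        expected = oracle_canonical_correlations(X, Y)
        assert np.abs(res.correlations - expected).max() < 1e-8

    @pytest.mark.parametrize("seed", range(8))
    def test_random_instances_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p, q = rng.integers(1, 5, size=2)
        X = rng.normal(size=(200, p))
        Y = 0.3 * X[:, :1] + rng.normal(size=(200, q))
        res = fit_cca(_std(X), _std(Y))
        expected = oracle_canonical_correlations(X, Y)
        assert np.abs(res.correlations - expected).max() < 1e-8

    def test_invariant_under_within_block_mixing(self, rng):
        X = rng.normal(size=(300, 3))
        Y = 0.5 * X[:, :2] + rng.normal(size=(300, 4))[:, :2] * 0.8
        Y = np.hstack([Y, rng.normal(size=(300, 2))])
        base = fit_cca(_std(X), _std(Y)).correlations
        for _ in range(5):
            mx = rng.normal(size=(3, 3)) + 3 * np.eye(3)
            my = rng.normal(size=(4, 4)) + 3 * np.eye(4)
            mixed = fit_cca(_std(X @ mx), _std(Y @ my)).correlations
            assert np.abs(mixed - base).max() < 1e-8

    def test_scale_shift_invariance(self, rng):
        X = rng.normal(size=(100, 2))
        Y = rng.normal(size=(100, 2)) + 0.4 * X
        base = fit_cca(_std(X), _std(Y))
        scaled = fit_cca(_std(X * [1000.0, 0.001] + 7.0), _std(Y))
        assert np.allclose(scaled.correlations, base.correlations, atol=1e-10)

    def test_loadings_and_cross_loading_identity(self, rng):
        X = rng.normal(size=(500, 3))
        Y = 0.6 * X[:, :2] + 0.8 * rng.normal(size=(500, 2))
        res = fit_cca(_std(X), _std(Y))
        assert np.all(np.abs(res.x_loadings.values) <= 1 + 1e-12)
        # cross-loading(v, k) = r_k * loading(v, k) on the same sample
        for k in range(len(res.correlations)):
            expected = res.correlations[k] * res.x_loadings.values[:, k]
            assert np.allclose(res.x_cross_loadings.values[:, k], expected, atol=1e-10)

    def test_sign_convention_deterministic(self, rng):
        X = rng.normal(size=(200, 3))
        Y = 0.5 * X + 0.9 * rng.normal(size=(200, 3))
        res = fit_cca(_std(X), _std(Y))
        for k in range(3):
            col = res.x_loadings.values[:, k]
            assert col[np.argmax(np.abs(col))] > 0
            # pair correlation nonnegative
            u = res.x_scores.values[:, k]
            v = res.y_scores.values[:, k]
            assert np.corrcoef(u, v)[0, 1] >= -1e-12

    def test_rank_deficient_block_advises_ridge(self, rng):
        x = rng.normal(size=(50, 1))
        X = np.hstack([x, x])  # perfectly collinear block
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            fit_cca(_std(X) * 1.0, _std(rng.normal(size=(50, 2))))
        res = fit_cca(_std(X), _std(rng.normal(size=(50, 2))), ridge=1e-6)
        assert np.all(res.correlations <= 1.0)


class TestProportions:
    def test_hand_arithmetic_pair(self):
        props = eigen_proportions(np.array([0.8, 0.6]))
        # lambda = (16/9, 9/16); shares 75.9644% / 24.0356%
        assert props == pytest.approx([75.96439, 24.03561], abs=1e-3)
        assert props.sum() == pytest.approx(100.0, abs=1e-9)

    def test_single_correlation_is_100(self):
        assert eigen_proportions(np.array([0.3]))[0] == pytest.approx(100.0)

    def test_unit_correlation_rejected(self):
        with pytest.raises(ValueError, match="infinite"):
            eigen_proportions(np.array([1.0]))

    def test_published_triple_consistency(self):
        # the convention lambda_k/sum(lambda) applied to reported canonical
        # correlations 0.800/0.436/0.415 must give a p3/p2 ratio compatible
        # with the reported 8.36/9.38 within print rounding
        props = eigen_proportions(np.array([0.800, 0.436, 0.415]))
        assert props[2] / props[1] == pytest.approx(8.36 / 9.38, abs=0.01)


class TestWilks:
    def test_null_is_flat(self):
        out = wilks_tests(np.zeros(2), n=50, p=2, q=2)
        assert np.allclose(out["wilks_lambda"], 1.0)
        assert np.allclose(out["chi2"], 0.0)
        assert np.allclose(out["p_value"], 1.0)

    def test_hand_arithmetic(self):
        out = wilks_tests(np.array([0.9, 0.1]), n=50, p=2, q=2)
        # Lambda_1 = 0.19 * 0.99 = 0.1881; scale = 50 - 1 - 2.5 = 46.5
        assert out.loc[0, "wilks_lambda"] == pytest.approx(0.1881)
        assert out.loc[0, "chi2"] == pytest.approx(46.5 * -np.log(0.1881), rel=1e-12)
        assert out.loc[0, "chi2"] == pytest.approx(77.7, abs=0.1)
        assert out.loc[0, "df"] == 4
        assert out.loc[1, "df"] == 1

    def test_type_i_error_rate_small(self):
        # smaller replicate count here; the full 500-replicate calibration
        # lives in the acceptance suite
        rejections = 0
        reps = 100
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            res = fit_cca(_std(rng.normal(size=(200, 2))), _std(rng.normal(size=(200, 2))))
            rejections += res.tests.loc[0, "p_value"] < 0.05
        lo, hi = stats.binom.ppf([0.005, 0.995], reps, 0.05)
        assert lo <= rejections <= hi


class TestPlantedRecovery:
    def test_recovery_single_seed(self):
        X, Y, truth = planted_cca_sample(5000, 8, 11, (0.8, 0.4, 0.2), seed=42)
        res = fit_cca(_std(X), _std(Y))
        assert np.abs(res.correlations[:3] - np.array(truth["rho"])).max() < 0.05

    def test_proportion_pattern_recovered(self):
        X, Y, truth = planted_cca_sample(5000, 4, 4, (0.8, 0.4, 0.2), seed=7)
        res = fit_cca(_std(X), _std(Y))
        expected = eigen_proportions(np.array(truth["rho"] + [0.0]))
        assert np.abs(res.proportions - expected).max() < 5.0
        assert res.proportions.sum() == pytest.approx(100.0, abs=1e-9)
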