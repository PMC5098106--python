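"""Unit and property tests for the EM fixed-point solvers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from l0em import (FitResult, RegressionData, SolverSettings,
                  check_contraction, dl0em_fit, em_fit, l0em_fit, lpem_fit,
                  objective, prune, ridge_init)
from conftest import brute_force_best_subset, orthonormal_instance, random_instance


class TestRegressionData:
    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="non-finite"):
            RegressionData(np.array([[1.0, np.nan], [0, 1]]), np.zeros(2))

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            RegressionData(np.eye(3), np.zeros(2))

    def test_rejects_single_sample(self):
        with pytest.raises(ValueError):
            RegressionData(np.ones((1, 2)), np.ones(1))


class TestRidgeInit:
    def test_identity_design(self):
        d = RegressionData(np.eye(5), np.ones(5))
        assert np.allclose(ridge_init(d, 1.0), 0.5)

    def test_zero_response(self):
        d = RegressionData(np.random.default_rng(0).standard_normal((6, 3)),
                           np.zeros(6))
        assert np.allclose(ridge_init(d, 0.5), 0.0)

    def test_primal_dual_identity(self):
        # n < m triggers the dual n x n form; it must agree with the
        # explicit m x m primal formula.
        r = np.random.default_rng(1)
        X = r.standard_normal((10, 20))
        y = r.standard_normal(10)
        d = RegressionData(X, y)
        theta_dual = ridge_init(d, 2.0)
        theta_primal = np.linalg.solve(X.T @ X + 2.0 * np.eye(20), X.T @ y)
        assert np.max(np.abs(theta_dual - theta_primal)) < 1e-10


class TestPrune:
    def test_thresholds(self):
        out = prune(np.array([1e-9, 0.5, -1e-7]), 1e-6)
        assert np.array_equal(out, [0.0, 0.5, 0.0])

    def test_zero_eps_identity(self):
        v = np.array([1e-30, -2.0, 0.1])
        assert np.array_equal(prune(v, 0.0), v)

    def test_large_eps_zeroes_everything(self):
        assert not np.any(prune(np.array([3.0, -5.0]), 1e12))


class TestObjective:
    def test_zero_theta(self):
        d = RegressionData(np.eye(3), np.array([1.0, 2, 2]))
        assert objective(d, np.zeros(3), 5.0) == pytest.approx(4.5)

    def test_interpolating_theta(self):
        # exact fit with k nonzeros leaves only the lam*k/2 penalty
        d = RegressionData(np.eye(3), np.array([1.0, 0, 2]))
        assert objective(d, np.array([1.0, 0, 2]), 3.0) == pytest.approx(3.0)


class TestL0EM:
    def test_zero_response_gives_empty_fit(self):
        d = RegressionData(np.random.default_rng(0).standard_normal((8, 4)),
                           np.zeros(8))
        fit = l0em_fit(d, SolverSettings(lam=1.0))
        assert fit.converged
        assert fit.support.size == 0
        assert fit.objective == 0.0

    def test_all_zero_user_init_rejected(self):
        d = random_instance(0, n=20, m=5)
        with pytest.raises(ValueError, match="trivial fixed point"):
            l0em_fit(d, SolverSettings(lam=1.0, init=np.zeros(5)))

    def test_orthonormal_design_closed_form(self):
        # With X'X = I the coordinates decouple: the nonzero fixed points of
        # t <- t^2 z/(t^2 + lam) are (z +/- sqrt(z^2 - 4 lam))/2, and from a
        # ridge start the iteration keeps coordinate j iff z_j^2 > 4 lam,
        # landing on the larger root.
        z = np.array([3.0, 2.5, 0.1, 0.05, 1.5])
        lam = 1.0
        d = orthonormal_instance(z)
        fit = l0em_fit(d, SolverSettings(lam=lam))
        keep = z**2 > 4 * lam
        assert set(fit.support.tolist()) == set(np.flatnonzero(keep).tolist())
        expected = (z[keep] + np.sqrt(z[keep] ** 2 - 4 * lam)) / 2
        assert np.max(np.abs(fit.theta[keep] - expected)) < 1e-6

    def test_null_model_above_lambda_max(self):
        # lam > max (x_j'y)^2 / (4 x_j'x_j) forces the empty model
        d = random_instance(3, n=30, m=6)
        X, y = d.X, d.y
        lam_max = np.max((X.T @ y) ** 2 / (4 * np.sum(X**2, axis=0)))
        fit = l0em_fit(d, SolverSettings(lam=1.01 * float(lam_max)))
        assert fit.support.size == 0

    def test_fixed_point_residual(self):
        # converged theta satisfies theta = (D X'X + lam I)^-1 D X'y
        d = random_instance(7, n=40, m=8)
        s = SolverSettings(lam=2.0)
        fit = l0em_fit(d, s)
        assert fit.converged
        D = fit.theta**2
        X, y = d.X, d.y
        G = np.linalg.solve(D[:, None] * (X.T @ X) + s.lam * np.eye(8),
                            D * (X.T @ y))
        assert np.max(np.abs(fit.theta - G)) <= 10 * s.tol

    def test_best_subset_oracle(self):
        # strong-signal instances: EM objective matches the exhaustive
        # best-subset minimum in >= 90% of instances and never beats it
        n, m = 30, 8
        lam = np.log(n)
        theta_true = np.array([2.0, -3.0, 0, 0, 4.0, 0, 0, 0])
        hits = 0
        n_inst = 100
        for seed in range(n_inst):
            r = np.random.default_rng(seed)
            X = r.standard_normal((n, m))
            y = X @ theta_true + 0.5 * r.standard_normal(n)
            d = RegressionData(X, y)
            fit = l0em_fit(d, SolverSettings(lam=lam))
            best_obj, best_sup = brute_force_best_subset(d, lam)
            assert fit.objective >= best_obj - 1e-9
            if fit.objective <= best_obj * 1.02:
                assert set(fit.support.tolist()) == set(best_sup)
                hits += 1
        assert hits >= 0.9 * n_inst

    def test_deterministic(self):
        d = random_instance(11, n=25, m=10)
        s = SolverSettings(lam=1.5)
        f1, f2 = l0em_fit(d, s), l0em_fit(d, s)
        assert np.array_equal(f1.theta, f2.theta)
        assert f1.n_iter == f2.n_iter and f1.objective == f2.objective

    def test_support_shrinks_monotonically(self):
        d = random_instance(13, n=30, m=12)
        fit = l0em_fit(d, SolverSettings(lam=3.0), history=True)
        supports = [set(np.flatnonzero(t).tolist()) for t in fit.history]
        for prev, nxt in zip(supports, supports[1:]):
            assert nxt <= prev

    def test_positive_only_clamps(self):
        d = random_instance(17, n=40, m=6)
        fit = l0em_fit(d, SolverSettings(lam=0.5, positive_only=True))
        assert np.all(fit.theta >= 0)


class TestDL0EM:
    @pytest.mark.parametrize("seed", range(50))
    def test_agrees_with_primal(self, seed):
        # primal-dual equivalence across random sizes n in [10,50], m in [5,200]
        d = random_instance(seed)
        s = SolverSettings(lam=1.0)
        fp = l0em_fit(d, s)
        fd = dl0em_fit(d, s)
        assert np.max(np.abs(fp.theta - fd.theta)) < 1e-8

    def test_zero_response(self):
        d = RegressionData(np.random.default_rng(0).standard_normal((5, 30)),
                           np.zeros(5))
        fit = dl0em_fit(d, SolverSettings(lam=1.0))
        assert fit.support.size == 0

    def test_highdim_spike_recovery(self):
        # n << m with 3 strong spikes: the dual fit recovers the spikes in
        # most replicates (interpolation-driven local optima make exact
        # recovery probabilistic at this sample size), and where it does the
        # support matches the best subset among the top marginal features
        n, m = 25, 200
        spikes = {3, 77, 150}
        lam = np.log(n)
        recovered = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.standard_normal((n, m))
            theta_true = np.zeros(m)
            theta_true[[3, 77, 150]] = [5.0, -6.0, 7.0]
            y = X @ theta_true + 0.1 * r.standard_normal(n)
            fit = dl0em_fit(RegressionData(X, y), SolverSettings(lam=lam))
            recovered.append(set(fit.support.tolist()) == spikes)
            if seed == 0:
                # brute force restricted to the top-10 marginal features
                top10 = np.argsort(-np.abs(X.T @ y))[:10]
                sub = RegressionData(X[:, top10], y)
                _, best_sub = brute_force_best_subset(sub, lam)
                assert {int(top10[j]) for j in best_sub} == spikes
        assert sum(recovered) >= 15

    def test_rejects_p_nonzero(self):
        d = random_instance(1, n=10, m=5)
        with pytest.raises(ValueError):
            dl0em_fit(d, SolverSettings(lam=1.0, p=1.0))


class TestLpEM:
    def test_p2_is_ridge(self):
        d = random_instance(2, n=30, m=6)
        fit = lpem_fit(d, SolverSettings(lam=2.0, p=2.0))
        ridge = np.linalg.solve(d.X.T @ d.X + 2.0 * np.eye(6), d.X.T @ d.y)
        assert np.max(np.abs(fit.theta - ridge)) < 1e-7
        assert fit.n_iter <= 2

    def test_p0_equals_l0em(self):
        d = random_instance(4, n=25, m=8)
        s = SolverSettings(lam=1.0, p=0.0)
        assert np.array_equal(lpem_fit(d, s, dual=False).theta,
                              l0em_fit(d, s).theta)

    def test_p1_matches_lasso_oracle(self):
        # the p=1 fixed point satisfies the stationarity conditions of
        # 1/2||y-X theta||^2 + lam ||theta||_1, i.e. sklearn Lasso with
        # alpha = lam / n (its objective divides the RSS by 2n)
        from sklearn.linear_model import Lasso

        n, m = 50, 10
        r = np.random.default_rng(1)
        X = r.standard_normal((n, m))
        theta_true = np.zeros(m)
        theta_true[[0, 3]] = [1.5, -2.0]
        y = X @ theta_true + 0.3 * r.standard_normal(n)
        lam = 5.0
        fit = lpem_fit(RegressionData(X, y),
                       SolverSettings(lam=lam, p=1.0, max_iter=5000))
        oracle = Lasso(alpha=lam / n, fit_intercept=False, tol=1e-12,
                       max_iter=200000).fit(X, y)
        assert np.max(np.abs(fit.theta - oracle.coef_)) < 1e-4


class TestCheckContraction:
    def test_zero_theta(self):
        d = random_instance(0, n=10, m=4)
        diag = check_contraction(d, np.zeros(4), 1.0)
        assert diag["gamma_bound"] == 0.0 and diag["satisfied"]

    def test_large_lambda_satisfied(self):
        d = random_instance(0, n=10, m=4)
        diag = check_contraction(d, np.ones(4), 1e8)
        assert diag["satisfied"]

    def test_satisfied_implies_monotone_gaps(self):
        # where the contraction bound holds, successive iterate gaps shrink
        d = random_instance(21, n=20, m=5)
        s = SolverSettings(lam=5.0)
        fit = l0em_fit(d, s, history=True)
        diag = check_contraction(d, fit.theta, s.lam)
        if diag["satisfied"]:
            gaps = [np.max(np.abs(b - a))
                    for a, b in zip(fit.history, fit.history[1:])]
            gaps = [g for g in gaps if g > 1e-13]
            assert all(b <= a * (1 + 1e-9) for a, b in zip(gaps, gaps[1:]))


@settings(derandomize=True, max_examples=30)
@given(st.lists(st.floats(-10, 10), min_size=1, max_size=8),
       st.floats(0, 1))
def test_prune_property(values, eps):
    out = prune(np.array(values), eps)
    arr = np.array(values)
    small = np.abs(arr) < eps
    assert np.all(out[small] == 0.0)
    assert np.array_equal(out[~small], arr[~small])
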