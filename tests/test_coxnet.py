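import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from tcoxnet import coxnet
from tcoxnet.coxnet import (
    cv_lambda,
    fit,
    hazard_ratio,
    lambda_path,
    neg_log_partial_likelihood,
    penalty_value,
    relative_risk,
)
from tcoxnet.survival import Survival
from tcoxnet.syndata import SyntheticConfig, generate_dataset


def toy_survival(n, rng, censor_frac=0.3):
    """Tie-free survival times with ~censor_frac censoring."""
    time = rng.exponential(100.0, size=n)
    time += rng.uniform(0, 1e-6, size=n)  # break ties
    event = (rng.uniform(size=n) > censor_frac).astype(int)
    if event.sum() == 0:
        event[0] = 1
    return Survival(time, event)


def breslow_oracle(beta, X, y):
    """Direct sum over risk sets, independent of the solver internals."""
    eta = X @ np.asarray(beta, dtype=float)
    total = 0.0
    for i in range(y.n):
        if y.event[i] == 1:
            risk = eta[y.time >= y.time[i]]
            total += eta[i] - np.log(np.sum(np.exp(risk)))
    return -total


class TestNegLogPartialLikelihood:
    def test_beta_zero_reduces_to_log_risk_set_sizes(self, rng):
        y = toy_survival(12, rng)
        X = rng.normal(size=(12, 3))
        expected = sum(
            np.log(np.sum(y.time >= y.time[i])) for i in range(12) if y.event[i]
        )
        got = neg_log_partial_likelihood(np.zeros(3), X, y, scale="sum")
        assert got == pytest.approx(expected)

    def test_three_sample_hand_instance(self):
        # times 1,2,3 all events, covariate (0,1,2), beta=1
        y = Survival([1.0, 2.0, 3.0], [1, 1, 1])
        X = np.array([[0.0], [1.0], [2.0]])
        e = np.exp
        expected = -(
            (0 - np.log(e(0) + e(1) + e(2)))
            + (1 - np.log(e(1) + e(2)))
            + (2 - np.log(e(2)))
        )
        got = neg_log_partial_likelihood(np.array([1.0]), X, y, scale="sum")
        assert got == pytest.approx(expected)
        assert got == pytest.approx(breslow_oracle([1.0], X, y))

    def test_invariant_to_covariate_shift(self, rng):
        y = toy_survival(15, rng)
        X = rng.normal(size=(15, 2))
        beta = np.array([0.7, -0.3])
        a = neg_log_partial_likelihood(beta, X, y)
        b = neg_log_partial_likelihood(beta, X + 5.0, y)
        assert a == pytest.approx(b, rel=1e-12)

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(5):
            y = toy_survival(10, rng)
            X = rng.normal(size=(10, 2))
            beta = rng.normal(size=2)
            assert neg_log_partial_likelihood(beta, X, y, scale="sum") == pytest.approx(
                breslow_oracle(beta, X, y)
            )

    def test_no_events_rejected(self):
        y = Survival([1.0, 2.0], [0, 0])
        with pytest.raises(ValueError, match="event"):
            neg_log_partial_likelihood(np.zeros(1), np.ones((2, 1)), y)


class TestPenaltyValue:
    def test_zero_beta(self):
        assert penalty_value(np.zeros(4), 2.0, 0.5) == 0.0

    def test_pure_lasso(self):
        assert penalty_value(np.array([1.0, -2.0]), 0.5, 1.0) == pytest.approx(1.5)

    def test_weighted_mixture(self):
        val = penalty_value(np.array([1.0, 1.0]), 1.0, 0.2, q=np.array([1.0, 2.0]))
        # 0.2 * (1 + 2) + 0.8 * (1 + 4)
        assert val == pytest.approx(4.6)


class TestFit:
    def test_huge_lambda_gives_exact_zeros(self, rng):
        y = toy_survival(30, rng)
        X = rng.normal(size=(30, 5))
        f = fit(X, y, lam=1e6, alpha=1.0)
        assert np.all(f.beta == 0.0)
        assert f.converged

    def test_unpenalized_matches_lifelines_newton(self, rng):
        y = toy_survival(40, rng, censor_frac=0.25)
        X = rng.normal(size=(40, 2))
        f = fit(X, y, lam=0.0)
        df = pd.DataFrame(X, columns=["a", "b"])
        df["T"], df["E"] = y.time, y.event
        oracle = CoxPHFitter().fit(df, "T", "E").params_.to_numpy()
        np.testing.assert_allclose(f.beta, oracle, atol=1e-5)

    def test_penalized_solution_beats_grid_oracle(self, rng):
        y = toy_survival(20, rng)
        X = rng.normal(size=(20, 2))
        lam, alpha = 0.1, 1.0
        f = fit(X, y, lam, alpha, standardize=False, rescale_q=False)

        def objective(b):
            return neg_log_partial_likelihood(b, X, y) + penalty_value(b, lam, alpha)

        grid = np.linspace(-2, 2, 200)
        # vectorized objective over the 200x200 grid
        B = np.array(np.meshgrid(grid, grid)).reshape(2, -1)
        eta = X @ B
        order = np.argsort(y.time)
        es = eta[order]
        rev = np.exp(es[::-1])
        risk = np.cumsum(rev, axis=0)[::-1]
        delta = y.event[order].astype(bool)
        ll = (es[delta] - np.log(risk[delta])).sum(axis=0)
        pen = lam * np.abs(B).sum(axis=0)
        grid_best = float((-ll / y.n + pen).min())
        assert objective(f.beta) <= grid_best + 1e-10

    def test_kkt_certificate_at_convergence(self, rng):
        y = toy_survival(60, rng)
        X = rng.normal(size=(60, 10))
        q = rng.uniform(0.5, 2.0, size=10)
        for lam, alpha in [(0.05, 1.0), (0.1, 0.2), (0.02, 0.0)]:
            f = fit(X, y, lam, alpha, q=q)
            assert f.converged
            assert f.kkt_violation < 1e-4

    def test_objective_trace_non_increasing(self, rng):
        y = toy_survival(50, rng)
        X = rng.normal(size=(50, 8))
        f = fit(X, y, 0.03, 0.5)
        assert np.all(np.diff(f.objective_trace) <= 1e-10)

    def test_ridge_limit_approaches_mle(self, rng):
        y = toy_survival(80, rng, censor_frac=0.2)
        X = rng.normal(size=(80, 2))
        mle = fit(X, y, 0.0).beta
        ridge = fit(X, y, 1e-6, alpha=0.0).beta
        np.testing.assert_allclose(ridge, mle, atol=1e-3)

    def test_lasso_q_equivariance(self, rng):
        # alpha=1: penalty factors q on X equal plain lasso on X scaled by 1/q
        y = toy_survival(40, rng)
        X = rng.normal(size=(40, 4))
        q = np.array([0.5, 1.0, 2.0, 1.5])
        lam = 0.05
        f_q = fit(X, y, lam, 1.0, q=q, standardize=False, rescale_q=False)
        f_s = fit(X / q, y, lam, 1.0, standardize=False, rescale_q=False)
        obj_q = neg_log_partial_likelihood(f_q.beta, X, y) + penalty_value(
            f_q.beta, lam, 1.0, q
        )
        obj_s = neg_log_partial_likelihood(f_s.beta, X / q, y) + penalty_value(
            f_s.beta, lam, 1.0
        )
        assert obj_q == pytest.approx(obj_s, abs=1e-8)

    def test_constant_feature_rejected(self, rng):
        y = toy_survival(10, rng)
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="constant"):
            fit(X, y, 0.1)


class TestLambdaPath:
    def test_all_zero_at_path_top(self, rng):
        y = toy_survival(50, rng)
        X = rng.normal(size=(50, 8))
        for alpha in (1.0, 0.2):
            path = lambda_path(X, y, alpha)
            f = fit(X, y, path[0], alpha)
            assert np.all(f.beta == 0.0)

    def test_grid_shape_and_ratio(self, rng):
        y = toy_survival(30, rng)
        X = rng.normal(size=(30, 4))
        path = lambda_path(X, y, 1.0, n_lambda=25, ratio=0.02)
        assert path.size == 25
        assert np.all(np.diff(path) < 0)
        assert path[-1] == pytest.approx(path[0] * 0.02)
        halved = lambda_path(X, y, 1.0, n_lambda=25, ratio=0.01)
        assert halved[-1] == pytest.approx(path[-1] * 0.5)

    def test_ridge_path_is_finite(self, rng):
        y = toy_survival(30, rng)
        X = rng.normal(size=(30, 4))
        path = lambda_path(X, y, 0.0)
        assert np.all(np.isfinite(path)) and np.all(path > 0)


class TestCvLambda:
    def test_seeded_determinism(self, rng):
        y = toy_survival(60, rng)
        X = rng.normal(size=(60, 6))
        a = cv_lambda(X, y, 0.5, k=5, seed=3)
        b = cv_lambda(X, y, 0.5, k=5, seed=3)
        assert a.lambda_selected == b.lambda_selected
        np.testing.assert_array_equal(a.fold_ids, b.fold_ids)
        np.testing.assert_allclose(a.cv_deviance, b.cv_deviance)

    def test_pure_noise_selects_sparse_models(self):
        """Under the null the deviance curve has no real dip.

        The 1-SE rule stays at the empty model essentially always; the min
        rule occasionally follows a small noise dip, so its guarantee is
        weaker (median model empty, small models in the large majority).
        """
        sizes_min, sizes_1se = [], []
        reps = 50
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            X = rng.normal(size=(100, 20))
            time = rng.exponential(100.0, size=100)
            event = (rng.uniform(size=100) > 0.3).astype(int)
            y = Survival(time, event)
            cv = cv_lambda(X, y, 1.0, k=10, seed=rep, n_lambda=30, ratio=0.05,
                           tol=1e-4)
            sizes_min.append(np.sum(fit(X, y, cv.lambda_min, 1.0).beta != 0))
            sizes_1se.append(np.sum(fit(X, y, cv.lambda_1se, 1.0).beta != 0))
        assert np.mean(np.array(sizes_1se) <= 1) >= 0.8
        assert np.median(sizes_min) == 0
        assert np.mean(np.array(sizes_min) <= 3) >= 0.8

    def test_strong_signal_gene_always_kept(self):
        cfg = SyntheticConfig(
            n_genes=10, n_tumor=300, n_normal=5, block_sizes=(),
            diffcorr_genes=frozenset(), de_genes={}, beta_true={0: 1.5},
            target_censoring=0.3, seed=2,
        )
        ds = generate_dataset(cfg)
        X = ds.expression[ds.tumor_samples()].to_numpy().T
        kept = 0
        reps = 20
        for rep in range(reps):
            cv = cv_lambda(X, ds.survival, 1.0, k=10, seed=rep, n_lambda=30,
                           ratio=0.05, tol=1e-4)
            f = fit(X, ds.survival, cv.lambda_selected, 1.0)
            kept += int(f.beta[0] != 0.0)
        assert kept >= 0.95 * reps

    def test_one_se_rule_is_sparser(self, rng):
        y = toy_survival(80, rng)
        X = rng.normal(size=(80, 10))
        res = cv_lambda(X, y, 1.0, k=5, seed=0)
        assert res.lambda_1se >= res.lambda_min


class TestDerivedQuantities:
    def test_relative_risk_reference_points(self):
        base = dict(
            lam=0.0, alpha=1.0, penalty_factor=np.ones(1), n_iter=1,
            converged=True, kkt_violation=0.0, neg_loglik=0.0,
        )
        f0 = coxnet.CoxFit(beta=np.zeros(2), **{**base, "penalty_factor": np.ones(2)})
        assert np.allclose(relative_risk(f0, np.random.default_rng(0).normal(size=(5, 2))), 1.0)
        f1 = coxnet.CoxFit(beta=np.array([1.0]), **base)
        assert relative_risk(f1, np.array([[np.log(2.0)]]))[0] == pytest.approx(2.0)
        f2 = coxnet.CoxFit(beta=np.array([0.5, -0.5]), **{**base, "penalty_factor": np.ones(2)})
        assert relative_risk(f2, np.array([[2.0, 2.0]]))[0] == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "beta,hr", [(0.0, 1.00), (0.1946, 1.21), (-0.2417, 0.79)]
    )
    def test_hazard_ratio(self, beta, hr):
        assert round(hazard_ratio(beta), 2) == pytest.approx(hr)

    def test_hazard_ratio_rejects_non_finite(self):
        with pytest.raises(ValueError):
            hazard_ratio(np.inf)
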