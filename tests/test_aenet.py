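import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from ersmix.aenet import (
    ConvergenceError,
    adaptive_weights,
    binomial_deviance,
    cv_fit,
    enet_logistic,
    kkt_violation,
    lambda_grid,
    lambda_max,
    stratified_folds,
)
from ersmix.expansion import expand, standardize
from ersmix.preprocess import log10_metals


def _logistic_data(rng, n=500, beta=(0.8, -0.5, 0.0), b0=0.2):
    X = rng.standard_normal((n, len(beta)))
    y = (rng.random(n) < expit(b0 + X @ np.asarray(beta))).astype(float)
    return X, y


def penalized_objective(X, y, b0, beta, lam, mix, w=None):
    """Direct evaluation of the penalized negative log-likelihood."""
    if w is None:
        w = np.ones(X.shape[1])
    eta = b0 + X @ beta
    nll = np.mean(np.logaddexp(0.0, eta) - y * eta)
    pen = lam * np.sum(w * (mix * np.abs(beta) + (1 - mix) / 2 * beta ** 2))
    return nll + pen


class TestEnetLogistic:
    def test_zero_penalty_equals_mle(self, rng):
        X, y = _logistic_data(rng)
        b0, b = enet_logistic(X, y, 0.0, 0.5)
        mle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(np.r_[b0, b], mle.params, atol=1e-6)

    def test_above_lambda_max_all_zero(self, rng):
        X, y = _logistic_data(rng)
        lmax = lambda_max(X, y, mix=0.7)
        b0, b = enet_logistic(X, y, lmax * 1.0001, 0.7)
        assert np.all(b == 0.0)
        assert b0 == pytest.approx(np.log(y.mean() / (1 - y.mean())), abs=1e-9)
        # just below lambda_max something must activate
        _, b2 = enet_logistic(X, y, lmax * 0.98, 0.7)
        assert np.any(b2 != 0.0)

    def test_grid_search_oracle_on_two_columns(self, rng):
        # 20x2 problem: the solver's penalized objective beats every point of
        # a 401x401 brute-force grid over [-2, 2]^2
        X = rng.standard_normal((20, 2))
        y = (rng.random(20) < expit(X @ np.array([1.0, -1.0]))).astype(float)
        lam, mix = 0.1, 0.5
        b0, b = enet_logistic(X, y, lam, mix)
        ours = penalized_objective(X, y, b0, b, lam, mix)
        g = np.linspace(-2, 2, 401)
        B1, B2 = np.meshgrid(g, g, indexing="ij")
        ETA = b0 + X[:, [0]] * B1.ravel() + X[:, [1]] * B2.ravel()
        nll = np.mean(np.logaddexp(0.0, ETA) - y[:, None] * ETA, axis=0)
        pen = lam * (mix * (np.abs(B1.ravel()) + np.abs(B2.ravel()))
                     + (1 - mix) / 2 * (B1.ravel() ** 2 + B2.ravel() ** 2))
        assert ours <= (nll + pen).min() + 1e-9

    def test_kkt_certificate_at_solutions(self, rng):
        X, y = _logistic_data(rng, n=300)
        for lam, mix in [(0.05, 0.5), (0.01, 0.9), (0.2, 0.1)]:
            b0, b = enet_logistic(X, y, lam, mix)
            assert kkt_violation(X, y, b0, b, lam, mix) < 1e-6

    def test_matches_sklearn_saga(self, rng):
        sklearn = pytest.importorskip("sklearn.linear_model")
        X, y = _logistic_data(rng, n=800, beta=(0.6, -0.4, 0.2))
        lam, mix = 0.02, 0.5
        b0, b = enet_logistic(X, y, lam, mix)
        clf = sklearn.LogisticRegression(
            penalty="elasticnet", solver="saga", l1_ratio=mix,
            C=1.0 / (len(y) * lam), max_iter=50_000, tol=1e-8)
        clf.fit(X, y)
        np.testing.assert_allclose(b, clf.coef_.ravel(), atol=5e-4)
        assert b0 == pytest.approx(clf.intercept_[0], abs=5e-4)

    def test_duplicated_column_contract(self, rng):
        X, y = _logistic_data(rng, n=400, beta=(0.9, 0.3, 0.0))
        lam = 0.02
        b0s, bs = enet_logistic(X, y, lam, 1.0)           # single copy
        Xd = np.column_stack([X, X[:, 0]])                # duplicate column 0
        b0d, bd = enet_logistic(Xd, y, lam, 1.0)
        assert bd[0] * bd[3] >= 0.0  # never opposite signs
        assert bd[0] + bd[3] == pytest.approx(bs[0], abs=1e-4)

    def test_validation_errors(self, rng):
        X, y = _logistic_data(rng, n=60)
        with pytest.raises(ValueError, match="binary"):
            enet_logistic(X, y + 0.5, 0.1, 0.5)
        with pytest.raises(ValueError, match="lambda"):
            enet_logistic(X, y, -0.1, 0.5)
        with pytest.raises(ValueError, match="weights"):
            enet_logistic(X, y, 0.1, 0.5, term_weights=[1.0, 0.0, 1.0])

    def test_nonconvergence_raises_with_sweep_count(self, rng):
        X, y = _logistic_data(rng, n=200)
        with pytest.raises(ConvergenceError, match="sweeps"):
            enet_logistic(X, y, 1e-6, 0.5, max_sweeps=2)


class TestAdaptiveWeights:
    def test_offset_arithmetic(self):
        assert adaptive_weights([0.0], gamma=1.0, n=100)[0] == pytest.approx(100.0)
        assert adaptive_weights([1.0], gamma=1.0, n=10**9)[0] == pytest.approx(1.0, abs=1e-8)

    def test_doubling_gamma_squares_weights(self):
        b = np.array([0.5, 2.0])
        w1 = adaptive_weights(b, gamma=1.0, n=10**9)
        w2 = adaptive_weights(b, gamma=2.0, n=10**9)
        np.testing.assert_allclose(w2, w1 ** 2, rtol=1e-6)

    def test_invalid_gamma(self):
        with pytest.raises(ValueError, match="gamma"):
            adaptive_weights([1.0], gamma=0.0, n=10)


class TestPathProperties:
    def test_training_deviance_non_increasing_in_lambda(self, rng):
        from ersmix.aenet import _fit_path, _gram
        X, y = _logistic_data(rng, n=400)
        Xf = np.asfortranarray(X)
        G, xm = _gram(Xf)
        w = np.ones(3)
        grid = lambda_grid(lambda_max(Xf, y, w, 0.5), 30, 1e-3)
        b0s, B, ok, _ = _fit_path(Xf, G, xm, y, w, 0.5, grid, 1e-7, 100_000)
        assert ok.all()
        devs = [binomial_deviance(b0s[k] + X @ B[k], y) for k in range(30)]
        assert np.all(np.diff(devs) <= 1e-9)

    def test_path_continuity_and_kkt(self, rng):
        from ersmix.aenet import _fit_path, _gram
        X, y = _logistic_data(rng, n=400)
        Xf = np.asfortranarray(X)
        G, xm = _gram(Xf)
        w = np.ones(3)
        grid = lambda_grid(lambda_max(Xf, y, w, 0.5), 50, 1e-3)
        b0s, B, ok, _ = _fit_path(Xf, G, xm, y, w, 0.5, grid, 1e-7, 100_000)
        jumps = np.abs(np.diff(B, axis=0)).max(axis=1)
        assert jumps.max() < 0.15  # warm-started path moves smoothly
        for k in range(0, 50, 7):
            assert kkt_violation(Xf, y, b0s[k], B[k], grid[k], 0.5, w) < 1e-5


class TestStratifiedFolds:
    def test_every_training_split_keeps_both_classes(self, rng):
        y = np.r_[np.ones(23), np.zeros(377)]
        fold = stratified_folds(y, 10, rng)
        assert len(fold) == 400
        for f in range(10):
            assert set(y[fold != f]) == {0.0, 1.0}
        sizes = np.bincount(fold)
        assert sizes.max() - sizes.min() <= 2

    def test_impossible_stratification_raises(self, rng):
        # a single case lands in one fold, whose training split then has no
        # cases; re-stratification cannot help and the error surfaces
        y = np.r_[np.ones(1), np.zeros(99)]
        with pytest.raises(ValueError, match="stratify"):
            stratified_folds(y, 10, rng)


@pytest.fixture(scope="module")
def small_fit(small_panel_cohort):
    metals = ["Ag", "Sb", "Sn", "La", "Ce"]
    Z, _ = standardize(log10_metals(small_panel_cohort, metals))
    ts = expand(Z, metals)
    return ts, cv_fit(ts, small_panel_cohort["depressed"].to_numpy(), seed=3)


class TestCvFit:
    def test_reproducible_given_seed(self, small_panel_cohort, small_fit):
        ts, fit = small_fit
        again = cv_fit(ts, small_panel_cohort["depressed"].to_numpy(), seed=3)
        np.testing.assert_array_equal(fit.final_coefficients,
                                      again.final_coefficients)
        np.testing.assert_array_equal(fit.fold_assignments, again.fold_assignments)
        assert fit.selected_alpha == again.selected_alpha
        assert fit.selected_lambda == again.selected_lambda

    def test_selected_terms_are_exactly_nonzero_coefs(self, small_fit):
        _, fit = small_fit
        nz = {lab for lab, b in zip(fit.term_labels, fit.final_coefficients)
              if b != 0.0}
        assert set(fit.selected_terms) == nz

    def test_recovers_strong_planted_terms(self, small_fit):
        # the generator planted Ag (0.9) and Sn^2 (-0.6) on 20 candidates
        _, fit = small_fit
        assert {"Ag", "Sn^2"} <= set(fit.selected_terms)
        coefs = fit.coefficients
        assert coefs["Ag"] > 0 and coefs["Sn^2"] < 0

    def test_adaptive_weights_positive_finite(self, small_fit):
        _, fit = small_fit
        assert np.all(fit.adaptive_weights > 0)
        assert np.all(np.isfinite(fit.adaptive_weights))

    def test_final_solution_satisfies_kkt(self, small_panel_cohort, small_fit):
        ts, fit = small_fit
        X = ts.values.to_numpy()
        y = small_panel_cohort["depressed"].to_numpy(float)
        assert kkt_violation(X, y, fit.intercept, fit.final_coefficients,
                             fit.selected_lambda, fit.selected_alpha,
                             fit.adaptive_weights) < 1e-5

    def test_cv_table_covers_both_stages(self, small_fit):
        _, fit = small_fit
        tab = fit.cv_deviance
        assert set(tab.stage) == {"stage1", "stage2"}
        assert {"alpha", "lambda", "mean_deviance", "se_deviance",
                "evaluated"} <= set(tab.columns)
        assert tab.loc[tab.evaluated, "mean_deviance"].notna().all()
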