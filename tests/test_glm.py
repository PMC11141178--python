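"""Logistic-regression core: IRLS, backward elimination, Nagelkerke, LASSO."""

import numpy as np
import pandas as pd
import pytest

from acnadi.errors import (
    CollinearityError,
    DegenerateInputError,
    StratificationError,
)
from acnadi.glm import (
    GlmFit,
    backward_eliminate,
    fit_lasso_cv,
    fit_logistic,
    nagelkerke_r2,
)


def test_intercept_only_closed_form():
    y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
    fit = fit_logistic(None, y)
    assert fit.coef[0] == pytest.approx(np.log(3 / 7), abs=1e-8)


def test_saturated_2x2_equals_log_odds_ratio():
    # table (20,10;10,20): OR = 4
    x = np.r_[np.ones(30), np.zeros(30)]
    y = np.r_[np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)]
    fit = fit_logistic(pd.DataFrame({"x": x}), y)
    assert fit.coef[1] == pytest.approx(np.log(4.0), abs=1e-8)


def test_irls_matches_dense_grid_search_oracle():
    """On a 6-point one-covariate problem the MLE from IRLS agrees with an
    exhaustive 2-D grid search over (intercept, slope)."""
    x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
    y = np.array([0.0, 0.0, 1.0, 0.0, 1.0, 1.0])
    fit = fit_logistic(pd.DataFrame({"x": x}), y)

    a_grid = np.linspace(-3, 3, 601)
    b_grid = np.linspace(-1, 4, 501)
    best, best_ll = None, -np.inf
    for a in a_grid:
        eta = a + np.outer(b_grid, x)
        ll = (y * eta - np.logaddexp(0, eta)).sum(axis=1)
        j = np.argmax(ll)
        if ll[j] > best_ll:
            best_ll, best = ll[j], (a, b_grid[j])
    assert fit.coef[0] == pytest.approx(best[0], abs=2e-2)
    assert fit.coef[1] == pytest.approx(best[1], abs=2e-2)
    # and the exact likelihood at the IRLS optimum is not worse than the grid's
    assert fit.log_likelihood >= best_ll - 1e-9


def test_matches_statsmodels_reference(logistic_data):
    import statsmodels.api as sm

    X, y = logistic_data
    fit = fit_logistic(X, y)
    ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    np.testing.assert_allclose(fit.coef, ref.params.values, atol=1e-8)
    np.testing.assert_allclose(fit.se, ref.bse.values, atol=1e-8)
    assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-8)


def test_single_class_outcome_raises():
    with pytest.raises(DegenerateInputError):
        fit_logistic(None, np.ones(10))


def test_collinear_design_names_aliased_term(rng):
    X = pd.DataFrame({"a": rng.standard_normal(50)})
    X["b"] = 2.0 * X["a"]
    y = (rng.random(50) < 0.5).astype(float)
    with pytest.raises(CollinearityError, match="b"):
        fit_logistic(X, y)


def test_separation_flag_on_perfectly_separated_data():
    x = np.r_[np.zeros(10), np.ones(10)]
    y = np.r_[np.zeros(10), np.ones(10)]
    fit = fit_logistic(pd.DataFrame({"x": x}), y)
    assert fit.separation_flag


def test_likelihood_ascent_and_exceeds_null(logistic_data):
    X, y = logistic_data
    fit = fit_logistic(X, y)
    assert fit.converged
    assert fit.log_likelihood >= fit.null_log_likelihood


def test_model_json_round_trip(logistic_data):
    X, y = logistic_data
    fit = fit_logistic(X, y)
    back = GlmFit.from_json(fit.to_json())
    np.testing.assert_allclose(back.predict(X), fit.predict(X), atol=1e-12)


class TestBackwardElimination:
    def test_fixed_point_when_all_significant(self, rng):
        n = 2000
        X = pd.DataFrame(rng.standard_normal((n, 2)), columns=["a", "b"])
        eta = -1.0 + 0.9 * X["a"] + 0.9 * X["b"]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        selected, fit = backward_eliminate(X, y)
        assert selected == ["a", "b"]

    def test_forced_term_with_large_p_is_retained(self, logistic_data):
        X, y = logistic_data
        selected, fit = backward_eliminate(X, y, forced={"d"})
        assert "d" in selected
        assert fit.pvalue("d") > 0.10  # genuinely non-significant, kept anyway

    def test_noise_terms_are_removed(self, logistic_data):
        X, y = logistic_data
        selected, _ = backward_eliminate(X, y)
        assert "a" in selected and "b" in selected
        assert "c" not in selected and "d" not in selected

    def test_order_invariance(self, logistic_data):
        X, y = logistic_data
        s1, _ = backward_eliminate(X, y)
        s2, _ = backward_eliminate(X[["d", "c", "b", "a"]], y)
        assert s1 == s2

    def test_true_predictor_retained_in_simulation(self):
        """A log-OR 0.8 predictor among 5 pure-noise predictors survives
        elimination in at least 95 of 100 replicates at n=2000."""
        kept = 0
        for rep in range(100):
            r = np.random.default_rng(5000 + rep)
            n = 2000
            X = pd.DataFrame(r.standard_normal((n, 6)),
                             columns=["sig"] + [f"n{i}" for i in range(5)])
            eta = -2.2 + 0.8 * X["sig"]
            y = (r.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            selected, _ = backward_eliminate(X, y)
            kept += "sig" in selected
        assert kept >= 95


class TestNagelkerke:
    def test_zero_for_intercept_only(self):
        y = np.r_[np.ones(5), np.zeros(15)]
        fit = fit_logistic(None, y)
        assert nagelkerke_r2(fit) == pytest.approx(0.0, abs=1e-10)

    def test_approaches_one_for_perfect_prediction(self):
        # near-saturated fit: likelihood close to 0
        x = np.r_[np.zeros(10), np.ones(10)]
        y = x.copy()
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert nagelkerke_r2(fit) > 0.95

    def test_matches_hand_formula(self, logistic_data):
        X, y = logistic_data
        fit = fit_logistic(X, y)
        n = fit.n
        r2_cs = 1 - np.exp((2 / n) * (fit.null_log_likelihood - fit.log_likelihood))
        expected = r2_cs / (1 - np.exp((2 / n) * fit.null_log_likelihood))
        assert nagelkerke_r2(fit) == pytest.approx(expected, abs=1e-12)


class TestLasso:
    def test_all_zero_at_lambda_max(self, logistic_data):
        X, y = logistic_data
        res = fit_lasso_cv(X, y, seed=0)
        assert np.all(np.abs(res.coef_path[0][1:]) < 1e-10)

    def test_smallest_lambda_approaches_unpenalized(self, logistic_data):
        X, y = logistic_data
        res = fit_lasso_cv(X, y, seed=0)
        Xs = (X - X.mean()) / X.std(ddof=0)
        ref = fit_logistic(Xs, y)
        np.testing.assert_allclose(res.coef_path[-1][1:], ref.coef[1:], atol=1e-3)

    def test_matches_sklearn_solution_along_path(self, logistic_data):
        from sklearn.linear_model import LogisticRegression

        X, y = logistic_data
        res = fit_lasso_cv(X, y, seed=0)
        Xs = ((X - X.mean()) / X.std(ddof=0)).to_numpy()
        n = len(y)
        for i in (5, 15, 25):
            lam = res.lambda_grid[i]
            ref = LogisticRegression(l1_ratio=1, C=1.0 / (n * lam), solver="saga",
                                     tol=1e-10, max_iter=50000).fit(Xs, y)
            np.testing.assert_allclose(res.coef_path[i][1:], ref.coef_[0], atol=1e-6)

    def test_sparsity_weakly_monotone_in_lambda(self, logistic_data):
        X, y = logistic_data
        res = fit_lasso_cv(X, y, seed=0)
        nnz = [(np.abs(c[1:]) > 1e-8).sum() for c in res.coef_path]  # grid descends
        assert all(a <= b for a, b in zip(nnz, nnz[1:]))

    def test_can_keep_all_predictors(self, rng):
        """With strong predictors only, the CV choice eliminates nothing —
        the redundancy check can return 'no predictor eliminated'."""
        n = 1500
        X = pd.DataFrame(rng.standard_normal((n, 3)), columns=["a", "b", "c"])
        eta = -1.5 + 0.8 * X["a"] + 0.7 * X["b"] - 0.6 * X["c"]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        res = fit_lasso_cv(X, y, seed=1)
        assert set(res.nonzero_set) == {"a", "b", "c"}

    def test_single_fold_class_raises(self):
        y = np.r_[np.ones(2), np.zeros(40)]
        X = pd.DataFrame({"x": np.arange(42.0)})
        with pytest.raises(StratificationError):
            fit_lasso_cv(X, y, folds=3, seed=0)
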