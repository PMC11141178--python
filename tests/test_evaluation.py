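"""Univariate screening, discrimination, calibration, trend."""

import numpy as np
import pandas as pd
import pytest

from acnadi.errors import DegenerateInputError
from acnadi.evaluation import (
    c_statistic,
    c_statistic_ci,
    calibration_by_quantile,
    hosmer_lemeshow,
    trend_test,
    univariate_screen,
)
from acnadi.glm import fit_logistic


def _cohort_from(x_binary, x_cont, y):
    return pd.DataFrame({"binvar": x_binary, "contvar": x_cont, "acn": y})


class TestUnivariateScreen:
    def test_null_2x2_table(self):
        x = np.r_[np.ones(20), np.zeros(20)]
        y = np.r_[np.ones(10), np.zeros(10), np.ones(10), np.zeros(10)]
        res = univariate_screen(_cohort_from(x, np.arange(40.0), y),
                                variables=["binvar"])[0]
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)

    def test_pearson_hand_arithmetic(self):
        # table (20,10;10,20): all expected cells 15, deviations +-5
        # chi2 = 4 * 25/15 = 6.667; OR = 4
        x = np.r_[np.ones(30), np.zeros(30)]
        y = np.r_[np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)]
        res = univariate_screen(_cohort_from(x, np.arange(60.0), y),
                                variables=["binvar"])[0]
        assert res.kind == "chi-square"
        assert res.statistic == pytest.approx(100 / 15, abs=1e-10)
        assert res.odds_ratio == pytest.approx(4.0, abs=1e-6)

    def test_welch_t_zero_for_identical_groups(self, rng):
        vals = rng.standard_normal(30)
        x_cont = np.r_[vals, vals]
        y = np.r_[np.ones(30), np.zeros(30)]
        res = univariate_screen(_cohort_from(np.r_[np.ones(30), np.zeros(30)][::-1] * 0
                                             + np.r_[np.ones(30), np.zeros(30)],
                                             x_cont, y), variables=["contvar"])[0]
        assert res.kind == "welch-t"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-12)


class TestCStatistic:
    def test_perfect_separation(self):
        assert c_statistic([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert c_statistic(np.full(10, 0.3), np.r_[np.ones(4), np.zeros(6)]) == 0.5

    def test_known_mixed_case(self):
        assert c_statistic([0.2, 0.4, 0.6, 0.8], [0, 1, 0, 1]) == pytest.approx(0.75)

    def test_equals_exhaustive_pair_enumeration(self, rng):
        pred = rng.random(80)
        pred[rng.integers(0, 80, 10)] = 0.5  # inject ties
        y = (rng.random(80) < 0.3).astype(int)
        conc = ties = 0
        for i in np.flatnonzero(y == 1):
            for j in np.flatnonzero(y == 0):
                if pred[i] > pred[j]:
                    conc += 1
                elif pred[i] == pred[j]:
                    ties += 1
        n_pairs = y.sum() * (len(y) - y.sum())
        assert c_statistic(pred, y) == pytest.approx((conc + 0.5 * ties) / n_pairs, abs=1e-14)

    def test_invariant_under_monotone_transform(self, rng):
        pred = rng.random(60)
        y = (rng.random(60) < 0.4).astype(int)
        assert c_statistic(pred, y) == pytest.approx(
            c_statistic(np.exp(3 * pred) - 1, y), abs=1e-14)

    def test_single_class_raises(self):
        with pytest.raises(DegenerateInputError):
            c_statistic([0.1, 0.2], [1, 1])


class TestCStatisticCI:
    @pytest.fixture
    def fitted(self, logistic_data):
        X, y = logistic_data
        return fit_logistic(X, y), X, y

    def test_deterministic_given_seed(self, fitted):
        fit, X, y = fitted
        a = c_statistic_ci(fit, X, y, B=200, seed=42)
        b = c_statistic_ci(fit, X, y, B=200, seed=42)
        assert a == b

    def test_degenerate_perfectly_separated_ci(self):
        x = np.r_[np.zeros(15), np.ones(15)]
        y = x.astype(int)
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        point, lo, hi = c_statistic_ci(fit, pd.DataFrame({"x": x}), y, B=100, seed=0)
        assert (point, lo, hi) == (1.0, 1.0, 1.0)

    def test_interval_covers_point(self, fitted):
        fit, X, y = fitted
        point, lo, hi = c_statistic_ci(fit, X, y, B=400, seed=3)
        assert lo <= point <= hi
        assert 0.5 < point < 1.0


class TestHosmerLemeshow:
    def test_perfect_calibration_gives_zero(self):
        # three groups, predictions equal to group rates
        pred = np.r_[np.full(10, 0.2), np.full(10, 0.5), np.full(10, 0.8)]
        y = np.r_[np.ones(2), np.zeros(8), np.ones(5), np.zeros(5), np.ones(8), np.zeros(2)]
        tab = hosmer_lemeshow(pred, y, labels=np.repeat([0, 1, 2], 10))
        assert tab.statistic == pytest.approx(0.0, abs=1e-12)
        assert tab.p == pytest.approx(1.0)

    def test_group_term_hand_arithmetic(self):
        """One group with n=10, mean prediction 0.2, 3 observed events
        contributes (3-2)^2 / (2 * (1 - 0.2)) = 0.625 to H."""
        pred = np.r_[np.full(10, 0.2), np.full(10, 0.5), np.full(10, 0.8)]
        y = np.r_[np.ones(3), np.zeros(7), np.ones(5), np.zeros(5), np.ones(8), np.zeros(2)]
        tab = hosmer_lemeshow(pred, y, labels=np.repeat([0, 1, 2], 10))
        assert tab.statistic == pytest.approx(0.625, abs=1e-12)
        assert tab.df == 1

    def test_p_from_chi_square_survival_closed_form(self):
        """H = 4 on df = 2 gives P = exp(-2)."""
        from scipy.stats import chi2

        assert chi2.sf(4.0, 2) == pytest.approx(np.exp(-2.0), abs=1e-12)
        # and the table's P uses that same reference
        pred = np.r_[np.full(50, 0.11), np.full(50, 0.3), np.full(50, 0.52), np.full(50, 0.7)]
        y = (np.arange(200) % 3 == 0).astype(float)
        tab = hosmer_lemeshow(pred, y, labels=np.repeat([0, 1, 2, 3], 50))
        assert tab.p == pytest.approx(float(chi2.sf(tab.statistic, tab.df)), abs=1e-12)

    def test_decile_grouping_accounts_everyone(self, logistic_data):
        X, y = logistic_data
        fit = fit_logistic(X, y)
        tab = hosmer_lemeshow(fit.predict(X), y)
        assert tab.table["n"].sum() == len(y)
        assert (tab.table["observed"] <= tab.table["n"]).all()
        assert tab.df == len(tab.table) - 2

    def test_statistic_nonnegative_and_zero_iff_perfect(self, logistic_data):
        X, y = logistic_data
        fit = fit_logistic(X, y)
        tab = hosmer_lemeshow(fit.predict(X), y)
        assert tab.statistic >= 0.0


class TestCalibrationByQuantile:
    def test_quartiles_of_eight_subjects(self):
        g = np.arange(8.0)
        pred = np.full(8, 0.5)
        y = np.r_[1, 0, 1, 0, 1, 0, 1, 0.0]
        tab = calibration_by_quantile(pred, y, g, Q=4)
        assert list(tab.table["n"]) == [2, 2, 2, 2]

    def test_perfect_group_calibration(self):
        g = np.repeat([1.0, 2.0, 3.0, 4.0], 10)
        rates = np.repeat([0.2, 0.4, 0.6, 0.8], 10)
        y = np.concatenate([np.r_[np.ones(int(10 * r)), np.zeros(10 - int(10 * r))]
                            for r in [0.2, 0.4, 0.6, 0.8]])
        tab = calibration_by_quantile(rates, y, g, Q=4)
        assert tab.p == pytest.approx(1.0)

    def test_too_few_distinct_values_raises(self):
        with pytest.raises(DegenerateInputError):
            calibration_by_quantile(np.full(8, 0.5), np.r_[np.ones(4), np.zeros(4)],
                                    np.ones(8), Q=4)


class TestTrendTest:
    def test_flat_prevalence_gives_zero(self):
        y = np.tile(np.r_[np.ones(2), np.zeros(8)], 3)
        g = np.repeat([1, 2, 3], 10)
        z, p = trend_test(y, g)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_strong_monotone_trend_significant(self):
        parts = []
        for rate in (0.05, 0.10, 0.15, 0.20):
            k = int(500 * rate)
            parts.append(np.r_[np.ones(k), np.zeros(500 - k)])
        y = np.concatenate(parts)
        g = np.repeat([1, 2, 3, 4], 500)
        _, p = trend_test(y, g)
        assert p < 1e-6

    def test_reversal_flips_sign_only(self):
        parts = []
        for rate in (0.05, 0.10, 0.20):
            k = int(200 * rate)
            parts.append(np.r_[np.ones(k), np.zeros(200 - k)])
        y = np.concatenate(parts)
        g = np.repeat([1, 2, 3], 200)
        z1, p1 = trend_test(y, g)
        z2, p2 = trend_test(y, 4 - g)
        assert z1 == pytest.approx(-z2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)
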