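"""Univariate screening and model-performance metrics.

Covers the evaluation surface of the risk-prediction workflow: chi-square /
Welch-t univariate screens with univariate odds ratios, the C-statistic
(area under the ROC curve) with a nonparametric bootstrap CI, the
Hosmer-Lemeshow goodness-of-fit statistic over deciles of predicted risk or
over explicit groups such as deprivation quantiles, and the Cochran-Armitage
trend test of prevalence across ordered groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata, ttest_ind

from .errors import DegenerateInputError
from .glm import GlmFit, fit_logistic

__all__ = [
    "UnivariateResult",
    "CalibrationTable",
    "univariate_screen",
    "c_statistic",
    "c_statistic_ci",
    "hosmer_lemeshow",
    "calibration_by_quantile",
    "trend_test",
]


@dataclass
class UnivariateResult:
    variable: str
    kind: str                  # "chi-square" or "welch-t"
    statistic: float
    p: float
    odds_ratio: float
    or_lower: float
    or_upper: float
    degenerate_table: bool = False  # zero margin; exact-test fallback used


def _pearson_chi2(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Pearson chi-square on the 2x2 table of binary x vs y, no continuity
    correction.  A zero margin triggers a Fisher-exact fallback, flagged."""
    tab = np.zeros((2, 2))
    for xi in (0, 1):
        for yi in (0, 1):
            tab[xi, yi] = np.sum((x == xi) & (y == yi))
    rows = tab.sum(axis=1)
    cols = tab.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        from scipy.stats import fisher_exact

        warnings.warn("degenerate 2x2 table (zero margin); Fisher exact fallback",
                      RuntimeWarning, stacklevel=3)
        _, p = fisher_exact(tab)
        return float("nan"), float(p), True
    expected = np.outer(rows, cols) / tab.sum()
    stat = float(np.sum((tab - expected) ** 2 / expected))
    return stat, float(chi2.sf(stat, 1)), False


def univariate_screen(
    cohort: pd.DataFrame,
    outcome: str = "acn",
    variables: list[str] | None = None,
) -> list[UnivariateResult]:
    """Screen each variable for univariate association with the outcome.

    Binary variables (two observed values) get a Pearson chi-square; the
    rest get a Welch unequal-variance t test comparing cases with controls.
    Every variable also gets an odds ratio with 95% Wald CI from a
    single-covariate logistic fit (binaries coded 0/1).
    """
    y = cohort[outcome].to_numpy(dtype=float)
    if variables is None:
        variables = [c for c in cohort.columns
                     if c not in (outcome, "subject_id", "tract_id", "race", "sex")]
    out: list[UnivariateResult] = []
    for var in variables:
        x = cohort[var].to_numpy(dtype=float)
        levels = np.unique(x)
        if len(levels) < 2:
            raise DegenerateInputError(f"variable '{var}' has a single observed value")
        degenerate = False
        if len(levels) == 2:
            xb = (x == levels[1]).astype(int)
            stat, p, degenerate = _pearson_chi2(xb, y.astype(int))
            kind = "chi-square"
            x_for_or = xb.astype(float)
        else:
            res = ttest_ind(x[y == 1], x[y == 0], equal_var=False)
            stat, p = float(res.statistic), float(res.pvalue)
            kind = "welch-t"
            x_for_or = x
        fit = fit_logistic(pd.DataFrame({var: x_for_or}), y)
        row = fit.odds_ratios().loc[var]
        out.append(UnivariateResult(
            variable=var, kind=kind, statistic=stat, p=p,
            odds_ratio=float(row["or"]), or_lower=float(row["or_lower"]),
            or_upper=float(row["or_upper"]), degenerate_table=degenerate,
        ))
    return out


def c_statistic(pred, y) -> float:
    """Concordance statistic: P(pred_event > pred_nonevent) counting ties as
    one half, over all event/non-event pairs.  Computed via the rank
    (Mann-Whitney) identity, which equals exhaustive pair enumeration."""
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise DegenerateInputError("C-statistic undefined for a single-class outcome")
    ranks = rankdata(pred)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def c_statistic_ci(
    model: GlmFit,
    X: pd.DataFrame,
    y,
    B: int = 2000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Bootstrap percentile CI for the C-statistic of a fitted model.

    Subjects are resampled with replacement ``B`` times; the (frozen) model
    is applied to each resample and the C-statistic recomputed.  Resamples
    with a single outcome class are redrawn; a warning reports the redraw
    count when it exceeds 10% of B.  Deterministic given the seed.
    """
    if B < 100:
        raise DegenerateInputError("need at least 100 bootstrap replicates")
    y = np.asarray(y, dtype=int)
    pred = model.predict(X)
    point = c_statistic(pred, y)
    rng = np.random.default_rng(seed)
    stats = np.empty(B)
    n = len(y)
    redraws = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if 0 < yb.sum() < n:
                break
            redraws += 1
        stats[b] = c_statistic(pred[idx], yb)
    if redraws > 0.1 * B:
        warnings.warn(f"{redraws} single-class bootstrap resamples redrawn", RuntimeWarning)
    lower, upper = np.percentile(stats, [2.5, 97.5])
    return point, float(lower), float(upper)


@dataclass
class CalibrationTable:
    """Observed-vs-expected event summary with a Hosmer-Lemeshow test."""

    table: pd.DataFrame        # per group: n, observed, mean_pred, expected, observed_rate
    statistic: float
    df: int
    p: float
    grouping: str              # e.g. "risk-decile" or "adi-quantile-4"


def _hl_from_groups(pred: np.ndarray, y: np.ndarray, labels: np.ndarray,
                    grouping: str) -> CalibrationTable:
    rows = []
    H = 0.0
    for g in np.unique(labels):
        m = labels == g
        n_g = int(m.sum())
        o_g = float(y[m].sum())
        mean_pred = float(pred[m].mean())
        e_g = float(pred[m].sum())
        if e_g <= 0 or e_g >= n_g:
            raise DegenerateInputError(
                f"group {g}: expected events {e_g:.3g} of {n_g} make the HL term "
                "undefined; merge groups"
            )
        H += (o_g - e_g) ** 2 / (e_g * (1.0 - e_g / n_g))
        rows.append({"group": g, "n": n_g, "observed": o_g,
                     "mean_pred": mean_pred, "expected": e_g,
                     "observed_rate": o_g / n_g})
    G = len(rows)
    if G < 3:
        raise DegenerateInputError(f"need at least 3 groups after merging (got {G})")
    df = G - 2
    return CalibrationTable(
        table=pd.DataFrame(rows),
        statistic=float(H),
        df=df,
        p=float(chi2.sf(H, df)),
        grouping=grouping,
    )


def hosmer_lemeshow(pred, y, groups=10, labels=None) -> CalibrationTable:
    """Hosmer-Lemeshow goodness-of-fit test.

    H = sum_g (O_g - E_g)^2 / (E_g (1 - E_g / n_g)), df = G - 2.

    By default subjects are grouped into deciles of predicted risk
    (``groups`` quantile cuts; tied cut points are merged).  Passing
    ``labels`` instead groups by the supplied explicit labels, e.g. ADI
    quartile membership.
    """
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    if labels is not None:
        return _hl_from_groups(pred, y, np.asarray(labels), "explicit")
    qs = np.quantile(pred, np.linspace(0, 1, groups + 1)[1:-1])
    cuts = np.unique(qs)
    lab = np.searchsorted(cuts, pred, side="right")
    return _hl_from_groups(pred, y, lab, f"risk-decile-{groups}")


def calibration_by_quantile(pred, y, group_var, Q: int = 4) -> CalibrationTable:
    """Calibration table across quantile groups of ``group_var`` (e.g. ADI).

    Cuts ``group_var`` at its sample quantiles into ``Q`` groups and runs
    the Hosmer-Lemeshow test with those explicit groups, yielding the
    observed rate vs mean predicted risk per deprivation stratum.
    """
    g = np.asarray(group_var, dtype=float)
    if Q < 2:
        raise DegenerateInputError("need at least 2 quantile groups")
    try:
        labels = pd.qcut(g, Q, labels=False, duplicates="raise")
    except ValueError as exc:
        raise DegenerateInputError(
            f"cannot form {Q} distinct quantile groups of the grouping variable"
        ) from exc
    tab = _hl_from_groups(np.asarray(pred, dtype=float), np.asarray(y, dtype=float),
                          np.asarray(labels), f"adi-quantile-{Q}")
    return tab


def trend_test(y, ordered_group_index) -> tuple[float, float]:
    """Cochran-Armitage test for trend in prevalence across ordered groups.

    Uses equally spaced integer scores 1..Q; returns (Z, two-sided P).
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(ordered_group_index)
    groups = np.unique(g)
    if len(groups) < 3:
        raise DegenerateInputError("need at least 3 ordered groups for a trend test")
    scores = {grp: i + 1.0 for i, grp in enumerate(groups)}
    s = np.array([scores[v] for v in g])
    n = len(y)
    pbar = y.mean()
    n_g = np.array([np.sum(g == grp) for grp in groups])
    o_g = np.array([y[g == grp].sum() for grp in groups])
    s_g = np.array([scores[grp] for grp in groups])
    num = float(np.sum(s_g * (o_g - n_g * pbar)))
    var = pbar * (1 - pbar) * (np.sum(n_g * s_g ** 2) - (np.sum(n_g * s_g)) ** 2 / n)
    if var <= 0:
        raise DegenerateInputError("trend test variance is zero")
    z = num / np.sqrt(var)
    return float(z), float(2 * norm.sf(abs(z)))
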