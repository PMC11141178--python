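"""Fixed-effects logistic regression from first principles.

Maximum-likelihood fitting is done by iteratively reweighted least squares
(IRLS, i.e. Newton-Raphson on the log-likelihood) with step-halving so the
log-likelihood never decreases.  On top of the fitter sit the model-building
tools the risk-prediction workflow needs: Wald tests, backward elimination at
a fixed significance threshold, Nagelkerke's pseudo-R², and an L1-penalised
(LASSO) path with stratified cross-validation on AUC used as a redundancy
check for a selected predictor set.

Coefficients are on the log-odds scale, one unit of the covariate as given
(per year of age, per kg/m² of BMI, per weekly frequency, or per level of a
binary indicator).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .errors import CollinearityError, ConvergenceError, DegenerateInputError, StratificationError

__all__ = [
    "GlmFit",
    "LassoCvResult",
    "fit_logistic",
    "backward_eliminate",
    "nagelkerke_r2",
    "fit_lasso_cv",
]

_SEPARATION_BOUND = 10.0  # |log-odds| beyond which we suspect separation


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # sum y*eta - log(1+exp(eta)), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


@dataclass
class GlmFit:
    """A fitted fixed-effects logistic regression model."""

    terms: list[str]
    coef: np.ndarray
    cov: np.ndarray
    log_likelihood: float
    null_log_likelihood: float
    n: int
    converged: bool
    separation_flag: bool

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def z(self) -> np.ndarray:
        return self.coef / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.z))

    def pvalue(self, term: str) -> float:
        return float(self.pvalues[self.terms.index(term)])

    def odds_ratios(self, level: float = 0.95) -> pd.DataFrame:
        """Wald odds ratios with confidence intervals, one row per term."""
        zq = norm.ppf(0.5 + level / 2.0)
        se = self.se
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": se,
                "or": np.exp(self.coef),
                "or_lower": np.exp(self.coef - zq * se),
                "or_upper": np.exp(self.coef + zq * se),
                "p": self.pvalues,
            },
            index=self.terms,
        )

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted event probabilities for a covariate table.

        ``X`` must contain every non-intercept term of the model; extra
        columns are ignored.
        """
        eta = np.zeros(len(X), dtype=float)
        for name, beta in zip(self.terms, self.coef):
            if name == "intercept":
                eta += beta
            else:
                eta += beta * X[name].to_numpy(dtype=float)
        return expit(eta)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "logistic",
                "terms": self.terms,
                "coef": self.coef.tolist(),
                "cov": self.cov.tolist(),
                "log_likelihood": self.log_likelihood,
                "null_log_likelihood": self.null_log_likelihood,
                "n": self.n,
                "converged": self.converged,
                "separation_flag": self.separation_flag,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GlmFit":
        d = json.loads(text)
        return cls(
            terms=list(d["terms"]),
            coef=np.asarray(d["coef"], dtype=float),
            cov=np.asarray(d["cov"], dtype=float),
            log_likelihood=float(d["log_likelihood"]),
            null_log_likelihood=float(d["null_log_likelihood"]),
            n=int(d["n"]),
            converged=bool(d["converged"]),
            separation_flag=bool(d["separation_flag"]),
        )


def _build_design(X: pd.DataFrame | None, y: np.ndarray, add_intercept: bool) -> tuple[np.ndarray, list[str]]:
    if X is None or X.shape[1] == 0:
        mat = np.empty((len(y), 0))
        names: list[str] = []
    else:
        mat = X.to_numpy(dtype=float)
        names = [str(c) for c in X.columns]
    if add_intercept and "intercept" not in names:
        mat = np.column_stack([np.ones(len(y)), mat])
        names = ["intercept"] + names
    return mat, names


def _check_rank(mat: np.ndarray, names: list[str]) -> None:
    if mat.shape[1] == 0:
        return
    _, r = np.linalg.qr(mat)
    diag = np.abs(np.diag(r))
    scale = diag.max() if diag.size else 1.0
    if scale == 0 or np.any(diag < 1e-10 * scale):
        # rebuild incrementally to name the first aliased column
        kept: list[int] = []
        for j in range(mat.shape[1]):
            sub = mat[:, kept + [j]]
            if np.linalg.matrix_rank(sub) < len(kept) + 1:
                raise CollinearityError(
                    f"design is rank deficient: column '{names[j]}' is collinear with preceding columns"
                )
            kept.append(j)


def fit_logistic(
    X: pd.DataFrame | None,
    y,
    add_intercept: bool = True,
    max_iter: int = 100,
) -> GlmFit:
    """Fit a logistic regression by IRLS.

    Parameters
    ----------
    X : DataFrame or None
        Covariate table (one column per term).  ``None`` or an empty frame
        fits an intercept-only model.
    y : array-like of {0,1}
        Binary outcome.
    add_intercept : bool
        Prepend an intercept column (named ``intercept``) unless one is
        already present.

    Convergence is declared when the largest absolute score component falls
    below 1e-8 or the relative change in log-likelihood falls below 1e-10.
    """
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise DegenerateInputError("outcome contains a single class; logistic model is undefined")
    mat, names = _build_design(X, y, add_intercept)
    n, p = mat.shape
    if n <= p:
        raise DegenerateInputError(f"need more subjects ({n}) than model terms ({p})")
    _check_rank(mat, names)

    beta = np.zeros(p)
    if "intercept" in names:
        beta[names.index("intercept")] = np.log(y.mean() / (1.0 - y.mean()))
    eta = mat @ beta
    ll = _log_likelihood(eta, y)
    converged = False
    improving_at_stop = False
    for _ in range(max_iter):
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        score = mat.T @ (y - mu)
        if np.max(np.abs(score)) < 1e-8:
            converged = True
            break
        fisher = (mat * w[:, None]).T @ mat
        try:
            delta = np.linalg.solve(fisher, score)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by _check_rank
            raise CollinearityError("Fisher information is singular") from exc
        # step-halving: never let the likelihood decrease
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            eta_c = mat @ cand
            ll_c = _log_likelihood(eta_c, y)
            if ll_c >= ll - 1e-12:
                break
            step /= 2.0
        improving_at_stop = ll_c > ll + 1e-10
        rel_change = abs(ll_c - ll) / (abs(ll) + 1e-12)
        beta, eta = cand, eta_c
        ll = ll_c
        if rel_change < 1e-10:
            converged = True
            break
    separation = bool(np.any(np.abs(beta) > _SEPARATION_BOUND)) and (improving_at_stop or not converged)

    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    fisher = (mat * w[:, None]).T @ mat
    cov = np.linalg.inv(fisher)
    # intercept-only reference likelihood
    pbar = y.mean()
    ll0 = _log_likelihood(np.full(n, np.log(pbar / (1 - pbar))), y)
    return GlmFit(
        terms=names,
        coef=beta,
        cov=cov,
        log_likelihood=ll,
        null_log_likelihood=ll0,
        n=n,
        converged=converged,
        separation_flag=separation,
    )


def backward_eliminate(
    X: pd.DataFrame,
    y,
    alpha: float = 0.10,
    forced: set[str] | frozenset[str] = frozenset(),
) -> tuple[list[str], GlmFit]:
    """Backward elimination on Wald P values.

    Starting from the full candidate model, repeatedly removes the
    non-forced term with the largest Wald P among those with P > ``alpha``
    and refits, until every non-forced term has P <= ``alpha``.  Forced
    terms are never removed.  Ties in P are broken lexicographically by
    term name so the result does not depend on column order.
    """
    forced = set(forced)
    unknown = forced - set(map(str, X.columns))
    if unknown:
        raise DegenerateInputError(f"forced terms not among candidates: {sorted(unknown)}")
    current = sorted(map(str, X.columns))
    fit = fit_logistic(X[current], y)
    while True:
        removable = [
            t for t in current
            if t not in forced and fit.pvalue(t) > alpha
        ]
        if not removable:
            return current, fit
        # largest P first; lexicographic tie-break
        victim = max(removable, key=lambda t: (fit.pvalue(t), t))
        current = [t for t in current if t != victim]
        fit = fit_logistic(X[current] if current else None, y)


def nagelkerke_r2(fit: GlmFit) -> float:
    """Nagelkerke's pseudo-R²: Cox-Snell R² rescaled to a [0, 1] range.

    R²_CS = 1 - exp((2/n)(ll0 - ll1)); its maximum 1 - exp((2/n) ll0) is
    attained by a perfectly predictive model, and dividing by it yields the
    Nagelkerke value.
    """
    n = fit.n
    r2_cs = 1.0 - np.exp((2.0 / n) * (fit.null_log_likelihood - fit.log_likelihood))
    r2_max = 1.0 - np.exp((2.0 / n) * fit.null_log_likelihood)
    return float(r2_cs / r2_max)


# ---------------------------------------------------------------------------
# LASSO with cross-validation on AUC
# ---------------------------------------------------------------------------


@dataclass
class LassoCvResult:
    """L1-penalised logistic path with stratified CV on AUC."""

    lambda_grid: np.ndarray          # decreasing
    cv_auc: np.ndarray               # mean held-out AUC per lambda
    chosen_lambda: float
    nonzero_set: list[str]           # terms with nonzero standardized coef at chosen_lambda
    coef_path: np.ndarray = field(repr=False)  # (n_lambda, p) standardized coefficients


def _rank_auc(pred: np.ndarray, y: np.ndarray) -> float:
    """AUC via the rank / Mann-Whitney identity (ties handled)."""
    from scipy.stats import rankdata

    y = np.asarray(y)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise DegenerateInputError("AUC undefined for a single-class outcome")
    ranks = rankdata(pred)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _soft_threshold(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


def _lasso_path(
    Xs: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    max_outer: int = 60,
    tol: float = 1e-7,
) -> np.ndarray:
    """Coordinate descent on the IRLS quadratic approximation, warm-started
    along a decreasing lambda path.  ``Xs`` must be standardized; the
    intercept is unpenalised.  Returns (n_lambda, p+1): intercept first."""
    n, p = Xs.shape
    beta0 = float(np.log(y.mean() / (1 - y.mean())))
    beta = np.zeros(p)
    out = np.zeros((len(lambdas), p + 1))
    for li, lam in enumerate(lambdas):
        for _ in range(max_outer):
            eta = beta0 + Xs @ beta
            mu = expit(eta)
            w = np.clip(mu * (1 - mu), 1e-6, None)
            z = eta + (y - mu) / w
            # inner coordinate-descent passes on the weighted LS problem
            for _ in range(200):
                max_delta = 0.0
                resid = z - beta0 - Xs @ beta
                for j in range(p):
                    xj = Xs[:, j]
                    rho = np.sum(w * xj * (resid + xj * beta[j])) / n
                    denom = np.sum(w * xj * xj) / n
                    new = _soft_threshold(rho, lam) / denom
                    if new != beta[j]:
                        resid += xj * (beta[j] - new)
                        max_delta = max(max_delta, abs(new - beta[j]))
                        beta[j] = new
                new0 = beta0 + np.sum(w * resid) / np.sum(w)
                resid += beta0 - new0
                max_delta = max(max_delta, abs(new0 - beta0))
                beta0 = new0
                if max_delta < tol:
                    break
            eta_new = beta0 + Xs @ beta
            if np.max(np.abs(eta_new - eta)) < 1e-8:
                break
        out[li, 0] = beta0
        out[li, 1:] = beta
    return out


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment (0..folds-1) per subject, stratified on the outcome."""
    assign = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        assign[idx] = np.arange(len(idx)) % folds
    counts = np.zeros((folds, 2), dtype=int)
    for f in range(folds):
        counts[f, 0] = int(np.sum((assign == f) & (y == 0)))
        counts[f, 1] = int(np.sum((assign == f) & (y == 1)))
    if np.any(counts == 0):
        raise StratificationError("a cross-validation fold contains a single outcome class")
    return assign


def fit_lasso_cv(
    X: pd.DataFrame,
    y,
    folds: int = 3,
    seed: int = 0,
    n_lambda: int = 30,
) -> LassoCvResult:
    """LASSO logistic path with ``folds``-fold stratified CV scored by AUC.

    Covariates are standardized (mean 0, SD 1) and the intercept is left
    unpenalised.  The penalty grid descends three decades from lambda_max,
    the smallest penalty at which every coefficient is zero.  The chosen
    lambda maximises mean held-out AUC; ties are broken toward the larger
    penalty (sparser model).
    """
    if folds < 2:
        raise StratificationError("need at least 2 folds")
    y = np.asarray(y, dtype=float)
    names = [str(c) for c in X.columns]
    raw = X.to_numpy(dtype=float)
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0)
    if np.any(sd == 0):
        bad = names[int(np.flatnonzero(sd == 0)[0])]
        raise DegenerateInputError(f"zero-variance covariate '{bad}' cannot be standardized")
    Xs = (raw - mean) / sd
    n = len(y)

    lam_max = float(np.max(np.abs(Xs.T @ (y - y.mean()))) / n)
    lambdas = np.geomspace(lam_max, lam_max * 1e-3, n_lambda)

    rng = np.random.default_rng(seed)
    assign = _stratified_folds(y, folds, rng)
    aucs = np.zeros((folds, len(lambdas)))
    for f in range(folds):
        tr = assign != f
        te = ~tr
        path = _lasso_path(Xs[tr], y[tr], lambdas)
        for li in range(len(lambdas)):
            eta = path[li, 0] + Xs[te] @ path[li, 1:]
            aucs[f, li] = _rank_auc(eta, y[te])
    mean_auc = aucs.mean(axis=0)
    best = int(np.argmax(mean_auc))  # first max = largest lambda since grid is decreasing
    full_path = _lasso_path(Xs, y, lambdas)
    nonzero = [names[j] for j in range(len(names)) if abs(full_path[best, j + 1]) > 1e-8]
    return LassoCvResult(
        lambda_grid=lambdas,
        cv_auc=mean_auc,
        chosen_lambda=float(lambdas[best]),
        nonzero_set=nonzero,
        coef_path=full_path,
    )
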