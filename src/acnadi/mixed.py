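"""Random-intercept logistic regression by adaptive Gauss-Hermite quadrature.

The marginal likelihood of a cluster j with random intercept
``u_j ~ Normal(0, sigma^2)`` is

    L_j = \\int exp(h_j(u)) du,
    h_j(u) = sum_i [y_ij eta_ij - log(1 + e^{eta_ij})]
             - u^2 / (2 sigma^2) - 0.5 log(2 pi sigma^2),
    eta_ij = x_ij' beta + u.

Adaptive quadrature first locates each cluster's posterior mode ``u_hat_j``
and curvature by a (vectorised, damped) Newton search, then re-centres and
re-scales the Gauss-Hermite nodes there:

    log L_j ~= log(sqrt(2) tau_j) + logsumexp_k [ log w_k + z_k^2
                + h_j(u_hat_j + sqrt(2) tau_j z_k) ].

The outer maximisation over (beta, log sigma) uses L-BFGS-B with numeric
gradients; standard errors come from the central-difference Hessian of the
negative log-likelihood at the optimum.  The random-effect SD is
parameterised on the log scale to enforce positivity; fits that run to the
lower bound are reported as zero variance with a boundary flag.

On top of the fitter sit the two-stage deprivation augmentation (base
predicted risk per 0.1 plus ADI per 10 units, with a tract random
intercept), the likelihood-ratio test for nested fixed effects, and the
variance-partition statistic (Var_Null - Var_Full) / Var_Null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import chi2, norm

from .errors import ConvergenceError, DegenerateInputError
from .glm import GlmFit, fit_logistic

__all__ = [
    "MixedFit",
    "AugmentedModel",
    "fit_random_intercept_logistic",
    "augment_with_adi",
    "lrt_nested",
    "variance_partition",
]

_LOG_SIGMA_MIN = np.log(1e-4)
_LOG_SIGMA_MAX = np.log(5.0)
_BOUNDARY_SIGMA = 1.5e-4


@dataclass
class MixedFit:
    """A fitted random-intercept logistic regression."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    tract_sd: float
    log_likelihood: float
    q_points: int
    n: int
    n_clusters: int
    converged: bool
    boundary_flag: bool

    @property
    def tract_variance(self) -> float:
        return 0.0 if self.boundary_flag else self.tract_sd ** 2

    def predict_fixed(self, X: pd.DataFrame) -> np.ndarray:
        """Population-level predicted probabilities (random effect at 0)."""
        eta = np.zeros(len(X), dtype=float)
        for name, b in zip(self.terms, self.coef):
            eta += b if name == "intercept" else b * X[name].to_numpy(dtype=float)
        return expit(eta)

    def odds_ratios(self, level: float = 0.95) -> pd.DataFrame:
        zq = norm.ppf(0.5 + level / 2.0)
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "or": np.exp(self.coef),
                "or_lower": np.exp(self.coef - zq * self.se),
                "or_upper": np.exp(self.coef + zq * self.se),
            },
            index=self.terms,
        )


class _AgqLoglik:
    """Marginal AGQ log-likelihood as a callable of (beta, log sigma)."""

    def __init__(self, mat: np.ndarray, y: np.ndarray, codes: np.ndarray,
                 n_clusters: int, q_points: int):
        self.mat = mat
        self.y = y
        self.codes = codes
        self.J = n_clusters
        nodes, weights = np.polynomial.hermite.hermgauss(q_points)
        self.nodes = nodes
        self.logw = np.log(weights)
        self.cluster_events = np.bincount(codes, weights=y, minlength=n_clusters)

    def _cluster_loglik_terms(self, eta: np.ndarray) -> np.ndarray:
        """sum_i [y eta - log(1+e^eta)] per cluster for subject-level eta."""
        contrib = self.y * eta - np.logaddexp(0.0, eta)
        return np.bincount(self.codes, weights=contrib, minlength=self.J)

    def modes(self, eta0: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mode and curvature scale tau per cluster (damped Newton,
        vectorised across clusters)."""
        b = np.zeros(self.J)
        inv_var = 1.0 / (sigma * sigma)
        for _ in range(100):
            mu = expit(eta0 + b[self.codes])
            grad = self.cluster_events - np.bincount(self.codes, weights=mu, minlength=self.J) - b * inv_var
            w = np.bincount(self.codes, weights=mu * (1 - mu), minlength=self.J) + inv_var
            step = grad / w
            # dampen large steps; the objective is strictly concave in b
            step = np.clip(step, -4.0, 4.0)
            b = b + step
            if np.max(np.abs(grad)) < 1e-10:
                break
        mu = expit(eta0 + b[self.codes])
        w = np.bincount(self.codes, weights=mu * (1 - mu), minlength=self.J) + inv_var
        return b, 1.0 / np.sqrt(w)

    def __call__(self, beta: np.ndarray, log_sigma: float) -> float:
        sigma = float(np.exp(log_sigma))
        eta0 = self.mat @ beta
        bhat, tau = self.modes(eta0, sigma)
        # h_j evaluated at the shifted/scaled nodes, (q, J)
        const = -0.5 * np.log(2 * np.pi * sigma * sigma)
        hk = np.empty((len(self.nodes), self.J))
        for k, z in enumerate(self.nodes):
            u = bhat + np.sqrt(2.0) * tau * z
            hk[k] = (self._cluster_loglik_terms(eta0 + u[self.codes])
                     - u * u / (2 * sigma * sigma) + const)
        lse = logsumexp(hk + (self.logw + self.nodes ** 2)[:, None], axis=0)
        return float(np.sum(np.log(np.sqrt(2.0) * tau) + lse))


def fit_random_intercept_logistic(
    X: pd.DataFrame | None,
    y,
    cluster_ids,
    q_points: int = 10,
    add_intercept: bool = True,
    start: np.ndarray | None = None,
    fixed_log_sigma: float | None = None,
    max_outer_iter: int = 500,
) -> MixedFit:
    """Fit a logistic model with one Gaussian random intercept per cluster.

    Parameters
    ----------
    X : DataFrame or None
        Fixed-effect covariates; ``None`` fits intercept plus random effect.
    cluster_ids : array-like
        Cluster label per subject (e.g. census tract id).
    q_points : int
        Number of adaptive Gauss-Hermite nodes (10 reproduces the reference
        integration accuracy; saturation is reached well before 30).
    start : ndarray, optional
        Starting values ``[beta..., log sigma]``.
    fixed_log_sigma : float, optional
        Profile the fixed effects at a frozen random-effect SD.
    """
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise DegenerateInputError("outcome contains a single class")
    codes, uniques = pd.factorize(np.asarray(cluster_ids))
    if len(uniques) < 2:
        raise DegenerateInputError("need at least 2 clusters for a random intercept")

    from .glm import _build_design

    mat, names = _build_design(X, y, add_intercept)
    ll_fun = _AgqLoglik(mat, y, codes, len(uniques), q_points)

    if start is None:
        base = fit_logistic(X, y, add_intercept=add_intercept)
        start = np.append(base.coef, np.log(0.3))
    start = np.asarray(start, dtype=float)
    p = mat.shape[1]

    if fixed_log_sigma is not None:
        def nll(params):
            return -ll_fun(params, fixed_log_sigma)
        x0 = start[:p]
        bounds = [(None, None)] * p
    else:
        def nll(params):
            return -ll_fun(params[:p], params[p])
        x0 = start
        bounds = [(None, None)] * p + [(_LOG_SIGMA_MIN, _LOG_SIGMA_MAX)]

    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": max_outer_iter, "ftol": 1e-12, "gtol": 1e-8})
    if not res.success and res.nit >= max_outer_iter:
        raise ConvergenceError(f"mixed-model fit did not converge: {res.message}")

    if fixed_log_sigma is not None:
        beta = res.x
        log_sigma = fixed_log_sigma
    else:
        beta = res.x[:p]
        log_sigma = float(res.x[p])
    sigma = float(np.exp(log_sigma))
    boundary = sigma <= _BOUNDARY_SIGMA
    ll = float(-res.fun)

    se = _fixed_effect_se(nll if fixed_log_sigma is not None else None,
                          ll_fun, beta, log_sigma, boundary)
    return MixedFit(
        terms=names,
        coef=beta.copy(),
        se=se,
        tract_sd=sigma,
        log_likelihood=ll,
        q_points=q_points,
        n=len(y),
        n_clusters=len(uniques),
        converged=bool(res.success),
        boundary_flag=boundary,
    )


def _fixed_effect_se(nll_profile, ll_fun: _AgqLoglik, beta: np.ndarray,
                     log_sigma: float, boundary: bool) -> np.ndarray:
    """Wald SEs from the central-difference Hessian of the negative
    log-likelihood.  At a variance boundary the log-sigma direction is flat,
    so the Hessian is taken over the fixed effects only."""
    p = len(beta)
    if boundary or nll_profile is not None:
        params = beta.copy()

        def f(v):
            return -ll_fun(v, log_sigma)
    else:
        params = np.append(beta, log_sigma)

        def f(v):
            return -ll_fun(v[:p], v[p])

    h = 1e-5 * np.maximum(1.0, np.abs(params))
    m = len(params)
    H = np.zeros((m, m))
    f0 = f(params)
    for i in range(m):
        for j in range(i, m):
            if i == j:
                vp = params.copy(); vp[i] += h[i]
                vm = params.copy(); vm[i] -= h[i]
                H[i, i] = (f(vp) - 2 * f0 + f(vm)) / (h[i] ** 2)
            else:
                vpp = params.copy(); vpp[[i, j]] += [h[i], h[j]]
                vpm = params.copy(); vpm[i] += h[i]; vpm[j] -= h[j]
                vmp = params.copy(); vmp[i] -= h[i]; vmp[j] += h[j]
                vmm = params.copy(); vmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = (f(vpp) - f(vpm) - f(vmp) + f(vmm)) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov)[:p], 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return se


@dataclass
class AugmentedModel:
    """Two-stage deprivation augmentation of a base risk model.

    The fixed effects are the base-model predicted risk in units of 0.1
    (absolute probability scale) and the ADI in units of 10 score points,
    plus an intercept and a census-tract random intercept.
    """

    or_base_per_0p1: float
    or_base_ci: tuple[float, float]
    lrt_p_base: float
    or_adi_per_10: float
    or_adi_ci: tuple[float, float]
    lrt_p_adi: float
    tract_variance: float          # full model (with ADI)
    tract_variance_null: float     # null model (without ADI)
    adi_variance_share: float      # (Var_Null - Var_Full) / Var_Null
    full_fit: MixedFit
    null_fit: MixedFit


def _refit_if_worse(full: MixedFit, null: MixedFit, X, y, clusters, q_points) -> MixedFit:
    """Restart the full fit from the null optimum if the optimizer left it
    below the nested model (cannot happen at a true optimum)."""
    if full.log_likelihood >= null.log_likelihood - 1e-6:
        return full
    start = np.zeros(len(full.terms) + 1)
    for i, t in enumerate(full.terms):
        if t in null.terms:
            start[i] = null.coef[null.terms.index(t)]
    start[-1] = np.log(max(null.tract_sd, 2e-4))
    return fit_random_intercept_logistic(X, y, clusters, q_points=q_points, start=start)


def augment_with_adi(
    base_predictions,
    adi,
    y,
    cluster_ids,
    q_points: int = 10,
) -> AugmentedModel:
    """Augment a base risk model with the Area Deprivation Index.

    Fits the mixed model ``acn ~ predicted_risk/0.1 + ADI/10 + (1|tract)``
    together with the two nested null models needed for the per-predictor
    likelihood-ratio tests, and computes the share of tract-level variance
    accounted for by ADI.
    """
    pred = np.asarray(base_predictions, dtype=float)
    adi = np.asarray(adi, dtype=float)
    if np.any((pred <= 0) | (pred >= 1)):
        raise DegenerateInputError("base predictions must lie strictly in (0, 1)")
    if pred.min() == pred.max():
        raise DegenerateInputError("base predictions are constant")
    if np.any((adi < 0) | (adi > 100)):
        raise DegenerateInputError("ADI scores must lie in [0, 100]")

    X = pd.DataFrame({"base_risk_per_0p1": pred / 0.1, "adi_per_10": adi / 10.0})
    null = fit_random_intercept_logistic(X[["base_risk_per_0p1"]], y, cluster_ids, q_points=q_points)
    full = fit_random_intercept_logistic(X, y, cluster_ids, q_points=q_points)
    full = _refit_if_worse(full, null, X, y, cluster_ids, q_points)
    null_base = fit_random_intercept_logistic(X[["adi_per_10"]], y, cluster_ids, q_points=q_points)

    _, _, p_adi = lrt_nested(full, null)
    _, _, p_base = lrt_nested(full, null_base)

    ors = full.odds_ratios()
    rb = ors.loc["base_risk_per_0p1"]
    ra = ors.loc["adi_per_10"]
    return AugmentedModel(
        or_base_per_0p1=float(rb["or"]),
        or_base_ci=(float(rb["or_lower"]), float(rb["or_upper"])),
        lrt_p_base=p_base,
        or_adi_per_10=float(ra["or"]),
        or_adi_ci=(float(ra["or_lower"]), float(ra["or_upper"])),
        lrt_p_adi=p_adi,
        tract_variance=full.tract_variance,
        tract_variance_null=null.tract_variance,
        adi_variance_share=variance_partition(null.tract_variance, full.tract_variance)
        if null.tract_variance > 0 else float("nan"),
        full_fit=full,
        null_fit=null,
    )


def lrt_nested(full: MixedFit, null: MixedFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fixed effects.

    Returns (statistic, df, P) with statistic = 2 (ll_full - ll_null) and
    df the difference in fixed-term counts, referred to the chi-square
    upper tail.
    """
    if not set(null.terms) <= set(full.terms):
        raise DegenerateInputError("null model terms are not nested in the full model")
    stat = 2.0 * (full.log_likelihood - null.log_likelihood)
    if stat < -1e-6:
        raise ConvergenceError(
            f"full-model likelihood below nested null ({stat / 2:.6g}); optimization failure"
        )
    stat = max(stat, 0.0)
    df = len(full.terms) - len(null.terms)
    p = float(chi2.sf(stat, df)) if df > 0 else 1.0
    return stat, df, p


def variance_partition(var_null: float, var_full: float) -> float:
    """Share of cluster-level variance explained by the added covariate:
    (Var_Null - Var_Full) / Var_Null.  Negative values (the full model's
    variance exceeding the null's) are returned raw with a warning."""
    if var_null <= 0:
        raise DegenerateInputError("variance partition undefined for Var_Null = 0")
    share = (var_null - var_full) / var_null
    if share < 0:
        warnings.warn("negative variance-partition share: Var_Full exceeds Var_Null",
                      RuntimeWarning, stacklevel=2)
    return float(share)
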