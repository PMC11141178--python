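"""Synthetic census tracts and nested two-race screening cohort.

Tract socioeconomic indicators follow a single-factor model
``x_k = lambda * f + sqrt(1 - lambda^2) * eps_k`` with a standard-normal
deprivation factor ``f`` shared by all 17 indicators, so that the first
principal component of their correlation matrix carries a configurable share
of total variance.  Subjects are nested in tracts, with race-dependent
tract assignment shaping each stratum's realized deprivation distribution,
and binary outcomes drawn from the augmented-model form

    logit p = alpha_race + sum_k beta_k x_k + beta_ADI * (ADI / 10) + u_tract,

with ``u_tract ~ Normal(0, tract_sigma^2)`` and the stratum intercept
calibrated so the realized prevalence matches its target.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .adi import INDICATOR_COLUMNS, compute_adi
from .config import GeneratorConfig
from .errors import CalibrationError, ConfigurationError

__all__ = [
    "generate_tracts",
    "calibrate_intercept",
    "generate_cohort",
    "tract_sigma_for_adi_share",
]

COHORT_COLUMNS = [
    "subject_id", "tract_id", "race", "sex", "age", "bmi",
    "family_history_fdr", "smoking_years", "diabetes", "calcium_use",
    "red_meat_per_week", "alcohol_per_week", "adi", "acn",
]

# spawn indices of the per-stage child RNG streams (master SeedSequence)
_STAGE_TRACTS = 0
_STAGE_TRACT_EFFECTS = 1
_STAGE_ASSIGNMENT = 2
_STAGE_COVARIATES = 3
_STAGE_OUTCOMES = 4


def _child_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stage + 1)[stage])


def generate_tracts(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate ``config.n_tracts`` census tracts with 17 indicators.

    Deterministic given the seed (defaults to the config's master seed).
    The latent deprivation factor is kept as a bookkeeping column
    ``latent_f``; it is not an input to any downstream estimator.
    """
    config.validate()
    lam = config.factor_loading
    rng = _child_rng(config.seed if seed is None else seed, _STAGE_TRACTS)
    n = config.n_tracts
    f = rng.standard_normal(n)
    eps = rng.standard_normal((n, len(INDICATOR_COLUMNS)))
    X = lam * f[:, None] + np.sqrt(1.0 - lam * lam) * eps
    out = pd.DataFrame(X, columns=INDICATOR_COLUMNS)
    out.insert(0, "tract_id", [f"T{i:04d}" for i in range(1, n + 1)])
    out["latent_f"] = f
    return out


def calibrate_intercept(linear_terms, target_prevalence: float, tol: float = 1e-6) -> float:
    """Intercept alpha with mean_i expit(alpha + term_i) = target.

    Solved by bisection on a bracketing interval; the mean response is
    strictly increasing in alpha, so for finite terms any target in (0, 1)
    is attainable.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise CalibrationError("target prevalence must lie in (0, 1)")
    terms = np.asarray(linear_terms, dtype=float)
    if terms.size == 0 or not np.all(np.isfinite(terms)):
        raise CalibrationError("linear terms must be a non-empty finite array")

    def mean_risk(alpha: float) -> float:
        return float(expit(alpha + terms).mean())

    lo = -40.0 - terms.max()
    hi = 40.0 - terms.min()
    if not mean_risk(lo) < target_prevalence < mean_risk(hi):
        raise CalibrationError("prevalence target is unattainable for these terms")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        v = mean_risk(mid)
        if abs(v - target_prevalence) < tol:
            return mid
        if v < target_prevalence:
            lo = mid
        else:
            hi = mid
    raise CalibrationError("bisection failed to reach the requested tolerance")


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lower: float, upper: float, size: int) -> np.ndarray:
    """Truncated-normal draws whose REALIZED mean equals ``mean``.

    The configured moments describe the eligible (truncated) population, so
    the pre-truncation location is solved for such that the truncated
    distribution's mean hits the target; the scale is kept at ``sd``.
    """
    from scipy.optimize import brentq

    def trunc_mean(mu: float) -> float:
        a, b = (lower - mu) / sd, (upper - mu) / sd
        return float(truncnorm.mean(a, b, loc=mu, scale=sd))

    lo_mu, hi_mu = mean - 8.0 * sd, mean + 8.0 * sd
    if trunc_mean(lo_mu) > mean or trunc_mean(hi_mu) < mean:
        raise ConfigurationError(
            f"truncated-normal mean {mean} unattainable on [{lower}, {upper}] with sd {sd}"
        )
    mu = brentq(lambda m: trunc_mean(m) - mean, lo_mu, hi_mu, xtol=1e-10)
    a, b = (lower - mu) / sd, (upper - mu) / sd
    return truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def _assign_tracts(rng: np.random.Generator, tract_adi: np.ndarray,
                   mean: float, sd: float, n: int) -> np.ndarray:
    """Tract index per subject: draw a target deprivation level from a
    truncated normal on [0, 100] and take the tract with nearest ADI, so the
    stratum's realized ADI mean and SD track the configured targets."""
    targets = _trunc_normal(rng, mean, sd, 0.0, 100.0, n)
    order = np.argsort(tract_adi)
    sorted_adi = tract_adi[order]
    pos = np.searchsorted(sorted_adi, targets)
    pos = np.clip(pos, 1, len(sorted_adi) - 1)
    left = sorted_adi[pos - 1]
    right = sorted_adi[pos]
    nearest = np.where(targets - left <= right - targets, pos - 1, pos)
    return order[nearest]


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (tract table with ADI column, subject cohort).

    Identical config and seed give byte-identical tables.  Outcomes follow
    the augmented-model form documented in the module docstring, with the
    per-stratum intercept calibrated by :func:`calibrate_intercept` so that
    the expected prevalence over the realized linear predictors equals the
    stratum target.
    """
    config.validate()
    required = set(config.coefficients)
    needed = {"male", "age", "bmi", "family_history_fdr", "smoking_years",
              "diabetes", "calcium_use", "red_meat_per_week", "alcohol_per_week"}
    missing = needed - required
    if missing:
        raise ConfigurationError(f"coefficients mapping is missing terms: {sorted(missing)}")

    tracts = generate_tracts(config)
    adi_res = compute_adi(tracts)
    tracts = tracts.copy()
    tracts["adi"] = adi_res.adi_by_tract.to_numpy()
    tract_adi = tracts["adi"].to_numpy()

    rng_u = _child_rng(config.seed, _STAGE_TRACT_EFFECTS)
    u_tract = rng_u.standard_normal(config.n_tracts) * config.tract_sigma

    rng_assign = _child_rng(config.seed, _STAGE_ASSIGNMENT)
    rng_cov = _child_rng(config.seed, _STAGE_COVARIATES)
    rng_out = _child_rng(config.seed, _STAGE_OUTCOMES)

    beta = config.coefficients
    frames = []
    offset = 0
    for race in sorted(config.race_blocks):
        block = config.race_blocks[race]
        n = block.n_subjects
        tract_idx = _assign_tracts(rng_assign, tract_adi, block.adi_target_mean,
                                   block.adi_target_sd, n)
        age = _trunc_normal(rng_cov, block.age_mean, block.age_sd, 50.0, 80.0, n)
        bmi = _trunc_normal(rng_cov, block.bmi_mean, block.bmi_sd, 15.0, 60.0, n)
        smoking = _trunc_normal(rng_cov, block.smoking_years_mean, block.smoking_years_sd, 0.0, np.inf, n)
        red_meat = _trunc_normal(rng_cov, block.red_meat_mean, block.red_meat_sd, 0.0, np.inf, n)
        alcohol = _trunc_normal(rng_cov, block.alcohol_mean, block.alcohol_sd, 0.0, np.inf, n)
        female = rng_cov.random(n) < block.p_female
        famhx = (rng_cov.random(n) < block.p_family_history).astype(int)
        diabetes = (rng_cov.random(n) < block.p_diabetes).astype(int)
        calcium = (rng_cov.random(n) < block.p_calcium).astype(int)

        adi = tract_adi[tract_idx]
        terms = (
            beta["male"] * (~female)
            + beta["age"] * age
            + beta["bmi"] * bmi
            + beta["family_history_fdr"] * famhx
            + beta["smoking_years"] * smoking
            + beta["diabetes"] * diabetes
            + beta["calcium_use"] * calcium
            + beta["red_meat_per_week"] * red_meat
            + beta["alcohol_per_week"] * alcohol
            + config.adi_effect(race) * (adi / 10.0)
            + u_tract[tract_idx]
        )
        alpha = calibrate_intercept(terms, block.target_prevalence)
        acn = (rng_out.random(n) < expit(alpha + terms)).astype(int)

        frames.append(pd.DataFrame({
            "subject_id": [f"S{offset + i:05d}" for i in range(1, n + 1)],
            "tract_id": tracts["tract_id"].to_numpy()[tract_idx],
            "race": race,
            "sex": np.where(female, "female", "male"),
            "age": age,
            "bmi": bmi,
            "family_history_fdr": famhx,
            "smoking_years": smoking,
            "diabetes": diabetes,
            "calcium_use": calcium,
            "red_meat_per_week": red_meat,
            "alcohol_per_week": alcohol,
            "adi": adi,
            "acn": acn,
        }))
        offset += n
    cohort = pd.concat(frames, ignore_index=True)[COHORT_COLUMNS]
    return tracts, cohort


def tract_sigma_for_adi_share(share: float, adi_log_or_per_10: float, adi_sd: float) -> float:
    """Residual tract-intercept SD such that the deprivation term carries a
    given share of tract-level linear-predictor variance.

    With tract-level variance Var(beta_ADI * ADI/10) + sigma^2, solving
    share = Var_ADI / (Var_ADI + sigma^2) gives
    sigma = sqrt(Var_ADI * (1 - share) / share).
    """
    if not 0.0 < share < 1.0:
        raise ConfigurationError("variance share must lie in (0, 1)")
    var_adi = (adi_log_or_per_10 * adi_sd / 10.0) ** 2
    return float(np.sqrt(var_adi * (1.0 - share) / share))
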