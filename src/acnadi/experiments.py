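"""Reusable recovery experiments on synthetic cohorts.

Each experiment regenerates data from the configured study conditions,
runs the corresponding estimator, and reports what it recovered.  They are
used both by the test suite and by the reproduction script.

All randomness derives from a single base seed; per-replicate seeds are
spawned with fixed offsets and kept below 2**31.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .config import GeneratorConfig, aa_like_config, ea_like_config
from .evaluation import calibration_by_quantile
from .glm import fit_logistic
from .io import model_frame
from .mixed import augment_with_adi, fit_random_intercept_logistic, lrt_nested
from .simulate import generate_cohort, generate_tracts, tract_sigma_for_adi_share
from .adi import compute_adi

__all__ = [
    "EA_BASE_PREDICTORS",
    "AA_BASE_PREDICTORS",
    "child_seed",
    "recover_adi_or",
    "recover_adi_variance_share",
    "pc1_share_recovery",
    "lrt_null_rejections",
    "directional_miscalibration",
]

#: Base-model predictor sets of the race-specific risk models (the EA model
#: uses sex, age, BMI, first-degree family history, smoking years and
#: calcium; the AA model age, smoking years, diabetes and red meat).
EA_BASE_PREDICTORS = ["male", "age", "bmi", "family_history_fdr", "smoking_years", "calcium_use"]
AA_BASE_PREDICTORS = ["age", "smoking_years", "diabetes", "red_meat_per_week"]

_MOD = 2**31 - 1


def child_seed(base: int, offset: int) -> int:
    """Deterministic child seed below 2**31."""
    return int((base * 1_000_003 + offset * 7919 + 1) % _MOD)


def _fit_augmented(cfg: GeneratorConfig, predictors: list[str]):
    _, cohort = generate_cohort(cfg)
    X = model_frame(cohort)
    y = cohort["acn"].to_numpy()
    base = fit_logistic(X[predictors], y)
    pred = base.predict(X)
    return augment_with_adi(pred, cohort["adi"].to_numpy(), y,
                            cohort["tract_id"].to_numpy())


def recover_adi_or(race: str = "EA", n_seeds: int = 10, seed: int = 0) -> dict:
    """Recover the per-10-unit ADI odds ratio from the two-stage mixed fit.

    Simulates ``n_seeds`` cohorts from the stratum's default configuration
    (which encodes the stratum's published deprivation effect), fits the
    augmentation model to each and averages the estimated odds ratios.
    """
    maker = ea_like_config if race == "EA" else aa_like_config
    predictors = EA_BASE_PREDICTORS if race == "EA" else AA_BASE_PREDICTORS
    ors = []
    for k in range(n_seeds):
        cfg = maker(seed=child_seed(seed, k))
        aug = _fit_augmented(cfg, predictors)
        ors.append(aug.or_adi_per_10)
    cfg0 = maker()
    return {
        "true_or": math.exp(cfg0.adi_effect(race)),
        "mean_or": float(np.mean(ors)),
        "per_seed": [float(v) for v in ors],
        "n": cfg0.race_blocks[race].n_subjects,
    }


def recover_adi_variance_share(race: str = "EA", target_share: float | None = None,
                               n_seeds: int = 10, seed: int = 0) -> dict:
    """Recover (Var_Null - Var_Full)/Var_Null on cohorts whose generator is
    calibrated so the deprivation term truly carries ``target_share`` of
    tract-level linear-predictor variance.

    The tract-intercept SD is set from the share via
    :func:`tract_sigma_for_adi_share`; the share is estimated from the
    pooled (seed-averaged) null and full variance estimates, which is far
    more stable than per-seed ratios when cluster sizes are small.
    """
    maker = ea_like_config if race == "EA" else aa_like_config
    predictors = EA_BASE_PREDICTORS if race == "EA" else AA_BASE_PREDICTORS
    if target_share is None:
        target_share = 0.387 if race == "EA" else 0.106
    cfg0 = maker()
    block = cfg0.race_blocks[race]
    sigma = tract_sigma_for_adi_share(target_share, cfg0.adi_effect(race), block.adi_target_sd)
    import pandas as pd

    v_null, v_full = [], []
    for k in range(n_seeds):
        cfg = maker(seed=child_seed(seed, 500 + k))
        cfg.tract_sigma = sigma
        _, cohort = generate_cohort(cfg)
        X = model_frame(cohort)
        y = cohort["acn"].to_numpy()
        pred = fit_logistic(X[predictors], y).predict(X)
        tract = cohort["tract_id"].to_numpy()
        D = pd.DataFrame({"base_risk_per_0p1": pred / 0.1,
                          "adi_per_10": cohort["adi"].to_numpy() / 10.0})
        null = fit_random_intercept_logistic(D[["base_risk_per_0p1"]], y, tract)
        full = fit_random_intercept_logistic(D, y, tract)
        v_null.append(null.tract_variance)
        v_full.append(full.tract_variance)
    mean_null = float(np.mean(v_null))
    mean_full = float(np.mean(v_full))
    return {
        "target_share_pct": 100.0 * target_share,
        "share_pct": 100.0 * (mean_null - mean_full) / mean_null,
        "mean_var_null": mean_null,
        "mean_var_full": mean_full,
        "tract_sigma": sigma,
        "n": block.n_subjects,
    }


def pc1_share_recovery(seed: int = 0, target_share: float = 0.602) -> dict:
    """Empirical first-principal-component variance share of 598 synthetic
    tracts whose common factor loading is set from ``target_share`` by the
    equicorrelation eigenvalue identity share = (1 + 16 lambda^2)/17."""
    cfg = ea_like_config(seed=child_seed(seed, 900))
    lam = math.sqrt((target_share * 17 - 1.0) / 16.0)
    cfg.factor_loading = lam
    tracts = generate_tracts(cfg)
    res = compute_adi(tracts)
    return {
        "target_share_pct": 100.0 * target_share,
        "share_pct": 100.0 * res.pc1_variance_share,
        "factor_loading": lam,
        "n_tracts": cfg.n_tracts,
    }


def lrt_null_rejections(n_perm: int = 100, seed: int = 0, alpha: float = 0.05,
                        n_subjects: int = 700, n_tracts: int = 250) -> dict:
    """Size of the ADI likelihood-ratio test under a permuted (null) ADI.

    One EA-like cohort is generated at a reduced size; ADI is then permuted
    across subjects ``n_perm`` times, breaking any true deprivation effect
    while preserving the marginal ADI distribution.  The null model (base
    risk + tract intercept) does not involve ADI and is fitted once.
    """
    cfg = ea_like_config(seed=child_seed(seed, 300))
    cfg.n_tracts = n_tracts
    cfg.race_blocks["EA"].n_subjects = n_subjects
    _, cohort = generate_cohort(cfg)
    X = model_frame(cohort)
    y = cohort["acn"].to_numpy()
    base = fit_logistic(X[EA_BASE_PREDICTORS], y)
    pred = base.predict(X)
    tract = cohort["tract_id"].to_numpy()
    adi = cohort["adi"].to_numpy()

    import pandas as pd

    D = pd.DataFrame({"base_risk_per_0p1": pred / 0.1})
    null = fit_random_intercept_logistic(D, y, tract)
    rng = np.random.default_rng(child_seed(seed, 301))
    rejections = 0
    pvals = []
    for _ in range(n_perm):
        adi_perm = rng.permutation(adi)
        Dp = D.assign(adi_per_10=adi_perm / 10.0)
        full = fit_random_intercept_logistic(Dp, y, tract)
        if full.log_likelihood < null.log_likelihood - 1e-6:
            start = np.array([null.coef[0], null.coef[1], 0.0,
                              np.log(max(null.tract_sd, 2e-4))])
            full = fit_random_intercept_logistic(Dp, y, tract, start=start)
        _, _, p = lrt_nested(full, null)
        pvals.append(p)
        rejections += p < alpha
    return {"n_perm": n_perm, "alpha": alpha, "rejections": int(rejections),
            "pvals": [float(p) for p in pvals]}


def directional_miscalibration(n_seeds: int = 100, seed: int = 0,
                               with_mixed: bool = False,
                               n_subjects: int = 1457, n_tracts: int = 598) -> dict:
    """Calibration across ADI quartiles when the base model omits ADI.

    For each seed an EA-like cohort (with a true deprivation effect) is
    generated and the base model (without ADI) is fitted.  Counts how often
    the base model overestimates mean risk in the least-deprived quartile
    while underestimating it in the most-deprived quartile.  With
    ``with_mixed`` the ADI-augmented mixed model is also fitted and the
    count of seeds where the post-augmentation Hosmer-Lemeshow P across ADI
    quartiles exceeds the pre-augmentation P is reported.
    """
    import pandas as pd

    directional = 0
    improved = 0
    for k in range(n_seeds):
        cfg = ea_like_config(seed=child_seed(seed, 700 + k))
        cfg.n_tracts = n_tracts
        cfg.race_blocks["EA"].n_subjects = n_subjects
        _, cohort = generate_cohort(cfg)
        X = model_frame(cohort)
        y = cohort["acn"].to_numpy()
        adi = cohort["adi"].to_numpy()
        base = fit_logistic(X[EA_BASE_PREDICTORS], y)
        pred = base.predict(X)
        cal = calibration_by_quantile(pred, y, adi, Q=4)
        t = cal.table.sort_values("group")
        first, last = t.iloc[0], t.iloc[-1]
        if (first["mean_pred"] > first["observed_rate"]
                and last["mean_pred"] < last["observed_rate"]):
            directional += 1
        if with_mixed:
            D = pd.DataFrame({"base_risk_per_0p1": pred / 0.1, "adi_per_10": adi / 10.0})
            full = fit_random_intercept_logistic(D, y, cohort["tract_id"].to_numpy())
            cal_after = calibration_by_quantile(full.predict_fixed(D), y, adi, Q=4)
            improved += cal_after.p > cal.p
    out = {"n_seeds": n_seeds, "directional": int(directional)}
    if with_mixed:
        out["improved"] = int(improved)
    return out
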