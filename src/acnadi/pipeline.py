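"""End-to-end orchestration of the race-stratified risk-prediction analysis.

For each population (combined, EA-only, AA-only) the pipeline screens
candidate predictors, runs bootstrap stability selection, fits the final
logistic model (race forced into the combined model), checks redundancy
with cross-validated LASSO, evaluates discrimination and calibration on the
development population and on the complementary race stratum, augments the
base model with the Area Deprivation Index in a tract random-intercept
mixed model, and reports calibration across ADI quartiles before and after
augmentation together with the tract-variance partition.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import GeneratorConfig, default_config
from .errors import AcnAdiError
from .evaluation import (
    c_statistic,
    c_statistic_ci,
    calibration_by_quantile,
    hosmer_lemeshow,
    trend_test,
    univariate_screen,
)
from .glm import fit_lasso_cv, fit_logistic, nagelkerke_r2
from .io import model_frame
from .mixed import augment_with_adi
from .simulate import generate_cohort
from .stability import (
    DEFAULT_FORCED,
    bootstrap_frequencies,
    choose_final_predictors,
    screen_candidates,
)

__all__ = ["PipelineSettings", "run_pipeline", "cohort_summary"]

log = logging.getLogger("acnadi.pipeline")


@dataclass
class PipelineSettings:
    """Tunable knobs of the full analysis run.

    The defaults are the reference procedure: 1000 stability-selection
    bootstrap replicates, 2000 bootstrap datasets for the C-statistic CI,
    selection threshold 0.4 with the frequency-drop rule on, elimination
    and screening thresholds 0.10, ADI calibration over quartiles, and
    10-point adaptive quadrature.
    """

    b_stability: int = 1000
    b_cstat: int = 2000
    threshold: float = 0.4
    drop_rule: bool = True
    alpha: float = 0.10
    screen_p: float = 0.10
    adi_quantiles: int = 4
    q_points: int = 10
    lasso_folds: int = 3
    seed: int = 0


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def cohort_summary(cohort: pd.DataFrame) -> dict:
    """Table-1-shaped summary: per-race n, means/SDs, proportions, prevalence."""
    out = {}
    strata = {"All": cohort} | {r: g for r, g in cohort.groupby("race")}
    for name, g in strata.items():
        out[name] = {
            "n": len(g),
            "events": int(g["acn"].sum()),
            "prevalence": float(g["acn"].mean()),
            "female_pct": float((g["sex"] == "female").mean()),
            "age_mean": float(g["age"].mean()), "age_sd": float(g["age"].std()),
            "bmi_mean": float(g["bmi"].mean()), "bmi_sd": float(g["bmi"].std()),
            "smoking_years_mean": float(g["smoking_years"].mean()),
            "family_history_pct": float(g["family_history_fdr"].mean()),
            "diabetes_pct": float(g["diabetes"].mean()),
            "calcium_pct": float(g["calcium_use"].mean()),
            "red_meat_mean": float(g["red_meat_per_week"].mean()),
            "alcohol_mean": float(g["alcohol_per_week"].mean()),
            "adi_mean": float(g["adi"].mean()), "adi_sd": float(g["adi"].std()),
        }
    return out


def _evaluate_on(fit, cohort: pd.DataFrame, include_race: bool,
                 b_cstat: int, seed: int) -> dict:
    X = model_frame(cohort, include_race=include_race)
    y = cohort["acn"].to_numpy()
    pred = fit.predict(X)
    point, lo, hi = c_statistic_ci(fit, X, y, B=b_cstat, seed=seed)
    hl = hosmer_lemeshow(pred, y)
    return {
        "c_statistic": point, "c_ci": [lo, hi],
        "hl_statistic": hl.statistic, "hl_df": hl.df, "hl_p": hl.p,
    }


def _analyse_population(name: str, cohort: pd.DataFrame, include_race: bool,
                        settings: PipelineSettings, seed: int,
                        others: dict[str, pd.DataFrame]) -> dict:
    t0 = time.perf_counter()
    y = cohort["acn"].to_numpy()
    X = model_frame(cohort, include_race=include_race)
    model_cohort = pd.concat([X, cohort[["acn"]]], axis=1)

    forced = set(DEFAULT_FORCED)
    candidates = screen_candidates(model_cohort, outcome="acn", forced=forced,
                                   screen_p=settings.screen_p,
                                   variables=[c for c in X.columns])
    log.info("%s: %d candidate predictors", name, len(candidates))

    stab = bootstrap_frequencies(X, y, candidates, B=settings.b_stability,
                                 alpha=settings.alpha, seed=seed)
    final = choose_final_predictors(stab, threshold=settings.threshold,
                                    drop_rule=settings.drop_rule)
    if include_race and "race_aa" not in final:
        # race is forced into the combined model even when unselected
        final = sorted(final + ["race_aa"])

    fit = fit_logistic(X[final], y)
    lasso = fit_lasso_cv(X[final], y, folds=settings.lasso_folds, seed=seed + 1)
    eliminated = sorted(set(final) - set(lasso.nonzero_set))

    own_eval = _evaluate_on(fit, cohort, include_race, settings.b_cstat, seed + 2)
    cross = {}
    for other_name, other in others.items():
        cross[other_name] = _evaluate_on(fit, other, include_race,
                                         settings.b_cstat, seed + 3)

    pred = fit.predict(X)
    adi = cohort["adi"].to_numpy()
    tract = cohort["tract_id"].to_numpy()
    aug = augment_with_adi(pred, adi, y, tract, q_points=settings.q_points)

    cal_before = calibration_by_quantile(pred, y, adi, Q=settings.adi_quantiles)
    pred_after = aug.full_fit.predict_fixed(
        pd.DataFrame({"base_risk_per_0p1": pred / 0.1, "adi_per_10": adi / 10.0})
    )
    cal_after = calibration_by_quantile(pred_after, y, adi, Q=settings.adi_quantiles)
    labels = pd.qcut(adi, settings.adi_quantiles, labels=False, duplicates="drop")
    z_trend, p_trend = trend_test(y, labels)

    block = {
        "n": len(cohort),
        "events": int(y.sum()),
        "prevalence": float(y.mean()),
        "candidates": candidates,
        "selection_frequencies": stab.frequencies,
        "sorted_frequencies": stab.sorted_frequencies,
        "final_predictors": final,
        "multivariable": _jsonable(fit.odds_ratios().reset_index().rename(columns={"index": "term"})),
        "nagelkerke_r2": nagelkerke_r2(fit),
        "lasso": {
            "chosen_lambda": lasso.chosen_lambda,
            "nonzero_set": lasso.nonzero_set,
            "eliminated": eliminated,
        },
        "performance": {"own": own_eval, "cross": cross},
        "augmentation": {
            "or_base_per_0p1": aug.or_base_per_0p1,
            "or_base_ci": list(aug.or_base_ci),
            "lrt_p_base": aug.lrt_p_base,
            "or_adi_per_10": aug.or_adi_per_10,
            "or_adi_ci": list(aug.or_adi_ci),
            "lrt_p_adi": aug.lrt_p_adi,
            "tract_variance_full": aug.tract_variance,
            "tract_variance_null": aug.tract_variance_null,
            "adi_variance_share": aug.adi_variance_share,
            "c_statistic_after": c_statistic(pred_after, y),
        },
        "calibration_by_adi": {
            "before": {"p": cal_before.p, "table": _jsonable(cal_before.table)},
            "after": {"p": cal_after.p, "table": _jsonable(cal_after.table)},
        },
        "adi_trend": {"z": z_trend, "p": p_trend},
    }
    log.info("%s: analysed in %.1fs", name, time.perf_counter() - t0)
    return block


def run_pipeline(
    config: GeneratorConfig | None = None,
    cohort: pd.DataFrame | None = None,
    tracts: pd.DataFrame | None = None,
    settings: PipelineSettings | None = None,
) -> dict:
    """Run the full analysis and return the report as a plain dict.

    Either a generator ``config`` (a synthetic cohort is generated) or an
    ingested ``cohort`` table must be supplied.  All randomness derives
    from ``settings.seed`` through fixed per-stage offsets, so identical
    inputs give identical reports.  A failing population block is recorded
    as skipped with its error message rather than aborting the whole run.
    """
    settings = settings or PipelineSettings()
    if cohort is None:
        config = config or default_config(seed=settings.seed)
        tracts, cohort = generate_cohort(config)

    report: dict = {
        "provenance": {
            "seed": settings.seed,
            "b_stability": settings.b_stability,
            "b_cstat": settings.b_cstat,
            "n_tracts": int(cohort["tract_id"].nunique()),
        },
        "cohort_summary": cohort_summary(cohort),
        "univariate": _jsonable([vars(r) for r in univariate_screen(cohort)]),
        "populations": {},
    }

    races = sorted(cohort["race"].unique())
    plan: list[tuple[str, pd.DataFrame, bool, dict[str, pd.DataFrame]]] = []
    strata = {r: cohort[cohort["race"] == r].reset_index(drop=True) for r in races}
    if len(races) > 1:
        plan.append(("All", cohort, True, strata))
    for r in races:
        others = {o: strata[o] for o in races if o != r}
        plan.append((r, strata[r], False, others))

    failed = False
    for i, (name, sub, include_race, others) in enumerate(plan):
        try:
            report["populations"][name] = _analyse_population(
                name, sub, include_race, settings, settings.seed + 100 * (i + 1), others
            )
        except AcnAdiError as exc:
            log.error("population %s failed: %s", name, exc)
            report["populations"][name] = {"skipped": True, "error": str(exc)}
            failed = True
    report["status"] = "partial" if failed else "complete"
    return _jsonable(report)


def report_to_text(report: dict) -> str:
    """Human-readable rendering of the analysis report."""
    lines = []
    lines.append("ACN risk-prediction analysis report")
    lines.append("=" * 40)
    for race, s in report["cohort_summary"].items():
        lines.append(
            f"{race}: n={s['n']} events={s['events']} "
            f"prevalence={100 * s['prevalence']:.1f}% ADI={s['adi_mean']:.1f} ({s['adi_sd']:.1f})"
        )
    for name, block in report["populations"].items():
        lines.append("")
        lines.append(f"Population {name}")
        lines.append("-" * 40)
        if block.get("skipped"):
            lines.append(f"  SKIPPED: {block['error']}")
            continue
        lines.append(f"  final predictors: {', '.join(block['final_predictors'])}")
        lines.append(f"  Nagelkerke R2: {100 * block['nagelkerke_r2']:.1f}%")
        perf = block["performance"]["own"]
        lines.append(
            f"  C-statistic {perf['c_statistic']:.3f} "
            f"({perf['c_ci'][0]:.3f}-{perf['c_ci'][1]:.3f}), HL P={perf['hl_p']:.3f}"
        )
        aug = block["augmentation"]
        lines.append(
            f"  ADI OR/10 {aug['or_adi_per_10']:.2f} "
            f"({aug['or_adi_ci'][0]:.2f}-{aug['or_adi_ci'][1]:.2f}), LRT P={aug['lrt_p_adi']:.3f}"
        )
        share = aug["adi_variance_share"]
        if share is not None:
            lines.append(f"  ADI share of tract variance: {100 * share:.1f}%")
        cal = block["calibration_by_adi"]
        lines.append(
            f"  calibration across ADI quartiles: P={cal['before']['p']:.3f} before, "
            f"P={cal['after']['p']:.3f} after augmentation"
        )
    return "\n".join(lines) + "\n"


def save_report(report: dict, json_path, text_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    if text_path is not None:
        with open(text_path, "w") as fh:
            fh.write(report_to_text(report))
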