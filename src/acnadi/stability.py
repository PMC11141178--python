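"""Bootstrap stability selection of risk-model predictors.

The selection procedure: screen candidates by univariate association
(P < 0.10) united with a set of literature-established forced candidates;
then, for each of B bootstrap resamples of the cohort, fit the full
candidate logistic model and run backward elimination at alpha = 0.10; count
how often each candidate survives; finally keep candidates whose selection
frequency exceeds a threshold (default 0.4), optionally extended past the
largest drop in the ordered frequency plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CollinearityError, DegenerateInputError, SchemaError
from .evaluation import univariate_screen
from .glm import backward_eliminate

__all__ = [
    "DEFAULT_FORCED",
    "StabilityResult",
    "screen_candidates",
    "bootstrap_frequencies",
    "choose_final_predictors",
]

#: Established colorectal-cancer risk factors kept as candidates regardless
#: of their univariate significance.
DEFAULT_FORCED = frozenset({
    "male", "bmi", "alcohol_per_week", "smoking_years",
    "family_history_fdr", "red_meat_per_week",
})


@dataclass
class StabilityResult:
    """Per-candidate bootstrap selection frequencies."""

    candidates: list[str]
    selection_count: dict[str, int]
    B: int
    alpha: float
    seed: int
    redraws: int = 0   # failed resamples that were redrawn

    @property
    def frequencies(self) -> dict[str, float]:
        return {t: self.selection_count[t] / self.B for t in self.candidates}

    @property
    def sorted_frequencies(self) -> list[tuple[str, float]]:
        """Descending (term, frequency), frequency ties broken by name."""
        freq = self.frequencies
        return sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))


def screen_candidates(
    cohort: pd.DataFrame,
    outcome: str = "acn",
    forced: set[str] | frozenset[str] = DEFAULT_FORCED,
    screen_p: float = 0.10,
    variables: list[str] | None = None,
) -> list[str]:
    """Candidate predictors: univariate P < ``screen_p`` union forced set.

    ``variables`` restricts which columns are screened; by default every
    modelling column of the cohort is screened.  Forced terms must be valid
    columns of the (model-ready) cohort table.
    """
    forced = set(forced)
    unknown = forced - set(map(str, cohort.columns))
    if unknown:
        raise SchemaError(f"forced terms missing from the cohort table: {sorted(unknown)}")
    results = univariate_screen(cohort, outcome=outcome, variables=variables)
    screened = {r.variable for r in results if r.p < screen_p}
    return sorted(screened | forced)


def bootstrap_frequencies(
    X: pd.DataFrame,
    y,
    candidates: list[str] | None = None,
    B: int = 1000,
    alpha: float = 0.10,
    seed: int = 0,
    forced: set[str] | frozenset[str] = frozenset(),
) -> StabilityResult:
    """Selection frequency of each candidate over B bootstrap resamples.

    Each replicate resamples n subjects with replacement, fits the full
    candidate model and applies backward elimination at ``alpha``; the
    survivors' counts are incremented.  Resamples whose fit fails (single
    outcome class, collinear resampled design, or apparent separation) are
    redrawn so B effective replicates are always used; more than 20% failed
    draws aborts with a data-pathology error.  Deterministic given the seed.
    """
    if candidates is None:
        candidates = [str(c) for c in X.columns]
    if not candidates:
        raise DegenerateInputError("candidate set is empty")
    y = np.asarray(y, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    counts = {t: 0 for t in candidates}
    Xc = X[candidates]
    redraws = 0
    for _ in range(B):
        while True:
            idx = rng.integers(0, n, n)
            yb = y[idx]
            try:
                selected, fit = backward_eliminate(Xc.iloc[idx], yb, alpha=alpha, forced=forced)
                if fit.separation_flag:
                    raise DegenerateInputError("separation in bootstrap resample")
            except (DegenerateInputError, CollinearityError):
                redraws += 1
                if redraws > 0.2 * B + 5:
                    raise DegenerateInputError(
                        f"more than 20% of bootstrap resamples failed to fit ({redraws} redraws)"
                    )
                continue
            break
        for t in selected:
            counts[t] += 1
    return StabilityResult(
        candidates=list(candidates),
        selection_count=counts,
        B=B,
        alpha=alpha,
        seed=seed,
        redraws=redraws,
    )


def choose_final_predictors(
    result: StabilityResult,
    threshold: float = 0.4,
    drop_rule: bool = True,
) -> list[str]:
    """Final predictor rule over the ordered selection frequencies.

    The base set contains every term with frequency > ``threshold``.  With
    ``drop_rule`` on, the largest drop between consecutive sorted
    frequencies *below the threshold* is located (first occurrence on
    ties); the set is extended to every term above that drop, pulling in
    moderately frequent terms that sit above a clear cliff in the ordered
    frequency plot.  A zero largest gap (flat plateau) never extends the
    set.
    """
    ordered = result.sorted_frequencies
    final = {t for t, f in ordered if f > threshold}
    if drop_rule and len(ordered) > 1:
        freqs = [f for _, f in ordered]
        gaps = [(freqs[i] - freqs[i + 1], i)
                for i in range(len(freqs) - 1) if freqs[i] <= threshold]
        if gaps:
            gmax, i = max(gaps, key=lambda gi: (gi[0], -gi[1]))
            if gmax > 0:
                final |= {t for t, _ in ordered[: i + 1]}
    return sorted(final)
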