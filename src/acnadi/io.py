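"""Cohort/tract CSV ingestion, validation, and model serialization."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .adi import INDICATOR_COLUMNS, compute_adi
from .errors import SchemaError, ValidationError
from .glm import GlmFit
from .simulate import COHORT_COLUMNS

__all__ = [
    "write_tracts",
    "write_cohort",
    "read_cohort",
    "save_model",
    "load_model",
    "model_frame",
]

AGE_RANGE = (50.0, 80.0)  # screening-eligibility window

REQUIRED_SUBJECT_COLUMNS = [c for c in COHORT_COLUMNS if c != "adi"]

#: Model-ready numeric terms derivable from a cohort table.
MODEL_TERMS = [
    "male", "age", "bmi", "family_history_fdr", "smoking_years",
    "diabetes", "calcium_use", "red_meat_per_week", "alcohol_per_week",
]


def write_tracts(tracts: pd.DataFrame, path: str | Path) -> None:
    tracts.to_csv(path, index=False)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(
    subject_csv: str | Path,
    tract_csv: str | Path,
    dictionary: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate subject and tract tables, joining ADI by tract.

    ``dictionary`` optionally maps file column names to the canonical
    schema (e.g. ``{"BMI": "bmi"}``).  Rows with missing values are
    excluded complete-case with a warning; an out-of-range age or a
    subject referencing an unknown tract raises a validation error listing
    the offending row indices.
    """
    subjects = pd.read_csv(subject_csv)
    tracts = pd.read_csv(tract_csv)
    if dictionary:
        subjects = subjects.rename(columns=dictionary)
        tracts = tracts.rename(columns=dictionary)

    missing_tract_cols = [c for c in ["tract_id"] + INDICATOR_COLUMNS if c not in tracts.columns]
    if missing_tract_cols:
        raise SchemaError(f"tract table is missing columns: {missing_tract_cols}")
    missing_subj_cols = [c for c in REQUIRED_SUBJECT_COLUMNS if c not in subjects.columns]
    if missing_subj_cols:
        raise SchemaError(f"subject table is missing columns: {missing_subj_cols}")
    if tracts["tract_id"].duplicated().any():
        raise ValidationError("tract_id values are not unique in the tract table")

    n_missing = int(subjects[REQUIRED_SUBJECT_COLUMNS].isna().any(axis=1).sum())
    if n_missing:
        warnings.warn(f"excluding {n_missing} rows with missing values (complete-case)",
                      RuntimeWarning)
        subjects = subjects.dropna(subset=REQUIRED_SUBJECT_COLUMNS).reset_index(drop=True)

    bad_age = subjects.index[(subjects["age"] < AGE_RANGE[0]) | (subjects["age"] > AGE_RANGE[1])]
    if len(bad_age):
        raise ValidationError(
            f"age outside the {AGE_RANGE[0]:.0f}-{AGE_RANGE[1]:.0f} eligibility window "
            f"in rows {list(bad_age[:20])}"
        )
    if not set(np.unique(subjects["acn"])) <= {0, 1}:
        raise ValidationError("outcome column 'acn' must be binary 0/1")

    known = set(tracts["tract_id"])
    orphan = subjects.index[~subjects["tract_id"].isin(known)]
    if len(orphan):
        raise ValidationError(
            f"{len(orphan)} subjects reference unknown tracts, rows {list(orphan[:20])}"
        )

    if "adi" not in tracts.columns:
        tracts = tracts.copy()
        tracts["adi"] = compute_adi(tracts).adi_by_tract.to_numpy()
    adi_map = tracts.set_index("tract_id")["adi"]
    subjects = subjects.copy()
    subjects["adi"] = subjects["tract_id"].map(adi_map).to_numpy()
    return tracts, subjects[COHORT_COLUMNS]


def model_frame(cohort: pd.DataFrame, include_race: bool = False) -> pd.DataFrame:
    """Numeric model-ready covariate table derived from a cohort.

    ``male`` is coded 1 for male sex; with ``include_race``, ``race_aa``
    codes the AA stratum as 1.
    """
    out = pd.DataFrame(index=cohort.index)
    out["male"] = (cohort["sex"] == "male").astype(float)
    for c in MODEL_TERMS[1:]:
        out[c] = cohort[c].astype(float)
    if include_race:
        out["race_aa"] = (cohort["race"] == "AA").astype(float)
    return out


def save_model(fit: GlmFit, path: str | Path) -> None:
    Path(path).write_text(fit.to_json() + "\n")


def load_model(path: str | Path) -> GlmFit:
    return GlmFit.from_json(Path(path).read_text())
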