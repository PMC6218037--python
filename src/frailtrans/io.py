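"""Cohort file I/O and validation.

Cohort waves are plain CSV (UTF-8, header row, "NA" missing marker), one row
per participant-wave; the column layout is frozen in docs/schema.md.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .scoring import ThresholdSet

MISSING_MARKER = "NA"

STRING_COLUMNS = (
    "wave", "gender", "ethnicity", "marital_status", "education_level",
    "living_arrangement", "chronic_diseases", "gds_energy", "latent_state",
    "frailty_state",
)

POSITIVE_COLUMNS = (
    "weight_current", "weight_at25", "height",
    "walk_time_1", "walk_time_2",
)
NONNEGATIVE_COLUMNS = (
    "grip_left_1", "grip_left_2", "grip_right_1", "grip_right_2",
    "pase_score", "income_monthly", "dssi_score",
)

MMSE_ELIGIBILITY_MIN = 9


class CohortValidationError(ValueError):
    pass


def write_cohort(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, na_rep=MISSING_MARKER)


def read_cohort(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort file not found: {path}")
    df = pd.read_csv(path, na_values=[MISSING_MARKER], keep_default_na=True)
    for col in STRING_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype(object).where(df[col].notna(), None)
    return df


def validate_cohort(records: pd.DataFrame) -> None:
    """Raise on structurally invalid records (field-level invariants)."""
    problems = []
    if "age" in records.columns:
        age = records["age"].to_numpy(dtype=float)
        if np.any(age[~np.isnan(age)] < 60):
            problems.append("age below 60")
    for col in POSITIVE_COLUMNS:
        if col in records.columns:
            v = records[col].to_numpy(dtype=float)
            if np.any(v[~np.isnan(v)] <= 0):
                problems.append(f"nonpositive {col}")
    for col in NONNEGATIVE_COLUMNS:
        if col in records.columns:
            v = records[col].to_numpy(dtype=float)
            if np.any(v[~np.isnan(v)] < 0):
                problems.append(f"negative {col}")
    if "mmse_score" in records.columns:
        v = records["mmse_score"].to_numpy(dtype=float)
        if np.any((v[~np.isnan(v)] < 0) | (v[~np.isnan(v)] > 30)):
            problems.append("MMSE outside 0-30")
    if problems:
        raise CohortValidationError("; ".join(problems))


def filter_eligible(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the eligibility rule: MMSE below 9 is excluded at load.

    Returns (eligible, excluded); records with a missing MMSE are retained.
    """
    mmse = records["mmse_score"].to_numpy(dtype=float)
    ineligible = ~np.isnan(mmse) & (mmse < MMSE_ELIGIBILITY_MIN)
    return records.loc[~ineligible].copy(), records.loc[ineligible].copy()


def write_thresholds(thresholds: ThresholdSet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(thresholds.to_dict(), fh, sort_keys=True)


def read_thresholds(path) -> ThresholdSet:
    with open(path) as fh:
        return ThresholdSet.from_dict(yaml.safe_load(fh))
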