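"""Cohort CSV schema, validated reading, and writing.

One flat UTF-8 comma-separated file per cohort, header row, ``NA`` as the
missing-value sentinel.  Schema violations are collected across the whole
file and raised together with row and column locations.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

log = logging.getLogger(__name__)

NA = "NA"

_ITEM_COLS = [f"pih_item_{i}" for i in range(1, 13)]
_SF_COLS = ["sf_ma", "sf_mx", "sf_mse"]
_COUNT_COLS = [
    "unplanned_cv_admissions",
    "hf_admissions",
    "non_cv_admissions",
    "planned_procedures",
    "booked_appointments",
    "attended_appointments",
]
_FLAG_COLS = ["died", "ltfu", "dose_reduced", "dose_ceased", "wrf"]
_FLOAT_COLS = ["age", "egfr_baseline", "egfr_followup", "scr_baseline", "scr_followup"]

#: required columns, in canonical order
COLUMNS = (
    ["patient_id", "age", "sex", "comorbidity_count"]
    + _ITEM_COLS
    + _SF_COLS
    + _COUNT_COLS
    + _FLAG_COLS
    + ["follow_up_months"]
    + _FLOAT_COLS[1:]
)
#: optional columns appended when present
OPTIONAL_COLUMNS = ["latent_trait"]

_INT_COLS = (
    ["patient_id", "comorbidity_count"] + _ITEM_COLS + _SF_COLS + _COUNT_COLS + _FLAG_COLS + ["follow_up_months"]
)


def _validate(df: pd.DataFrame) -> list[str]:
    problems: list[str] = []

    def check(col, mask, msg):
        for row in df.index[mask][:10]:
            problems.append(f"row {row}, column {col}: {msg} (value {df.at[row, col]!r})")

    for col in _INT_COLS:
        vals = pd.to_numeric(df[col], errors="coerce")
        check(col, vals.isna(), "missing or non-numeric")
        ok = vals.notna()
        check(col, ok & (vals != np.floor(vals)), "not an integer")
    for col in _ITEM_COLS:
        vals = pd.to_numeric(df[col], errors="coerce")
        check(col, vals.notna() & ~vals.between(0, 8), "Likert response outside 0-8")
    for col in _SF_COLS + _FLAG_COLS:
        vals = pd.to_numeric(df[col], errors="coerce")
        check(col, vals.notna() & ~vals.isin([0, 1]), "must be 0 or 1")
    for col in _COUNT_COLS:
        vals = pd.to_numeric(df[col], errors="coerce")
        check(col, vals.notna() & (vals < 0), "negative count")
    for col in _FLOAT_COLS:
        vals = pd.to_numeric(df[col], errors="coerce")
        check(col, df[col].notna() & vals.isna(), "non-numeric")
    booked = pd.to_numeric(df["booked_appointments"], errors="coerce")
    attended = pd.to_numeric(df["attended_appointments"], errors="coerce")
    check("attended_appointments", booked.notna() & attended.notna() & (attended > booked), "attended exceeds booked")
    fup = pd.to_numeric(df["follow_up_months"], errors="coerce")
    check("follow_up_months", fup.notna() & ~fup.between(0, 12), "outside 0-12")
    sex_ok = df["sex"].isin(["M", "F"])
    check("sex", ~sex_ok, "must be 'M' or 'F'")
    return problems


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Raises :class:`SchemaError` listing every violation (capped per column)
    with its row and column.  An empty data section yields an empty frame
    with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False, na_values=[NA])
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError([f"missing column {c!r}" for c in missing])
    if len(df) == 0:
        log.warning("cohort file %s has a header but no rows", path)
        return df
    problems = _validate(df)
    if problems:
        raise SchemaError(problems)
    for col in _INT_COLS:
        df[col] = df[col].astype(int)
    for col in _FLOAT_COLS + [c for c in OPTIONAL_COLUMNS if c in df.columns]:
        df[col] = df[col].astype(float)
    log.info("read %d patients from %s", len(df), path)
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort CSV in canonical column order, ``NA`` for missing."""
    path = Path(path)
    cols = COLUMNS + [c for c in OPTIONAL_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df.to_csv(path, index=False, columns=cols + extra, na_rep=NA)
    log.info("wrote %d patients to %s", len(df), path)
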