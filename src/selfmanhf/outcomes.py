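"""Twelve-month outcome classification: readmission composite, worsening
renal function, attendance failure, and the per-category MACE summary.

The headline event is the admission composite -- any unplanned
cardiovascular admission, heart-failure admission, or death over follow-up.
Worsening renal function (WRF) is a >=25% fall in eGFR or, symmetrically, a
>=25% rise in serum creatinine.  Failure to attend (FTA) means missing more
than 25% of pre-booked appointments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .scrinhf import sf_categories

# closed admission-count bands; must partition the non-negative integers
ADMISSION_BANDS = [("0", 0, 0), ("1", 1, 1), ("2-3", 2, 3), ("4+", 4, None)]


@dataclass(frozen=True)
class OutcomeRecord:
    """One patient's 12-month outcome fields."""

    unplanned_cv_admissions: int
    hf_admissions: int
    non_cv_admissions: int = 0
    planned_procedures: int = 0
    died: bool = False
    ltfu: bool = False
    follow_up_months: int = 12
    booked_appointments: int = 0
    attended_appointments: int = 0
    dose_reduced: bool = False
    dose_ceased: bool = False
    wrf: bool = False
    egfr_baseline: float | None = None
    egfr_followup: float | None = None
    scr_baseline: float | None = None
    scr_followup: float | None = None

    def __post_init__(self):
        for name in (
            "unplanned_cv_admissions",
            "hf_admissions",
            "non_cv_admissions",
            "planned_procedures",
            "booked_appointments",
            "attended_appointments",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.attended_appointments > self.booked_appointments:
            raise ValidationError("attended appointments exceed booked")
        if not 0 <= self.follow_up_months <= 12:
            raise ValidationError("follow_up_months must be in 0..12")


def readmission_flag(rec: OutcomeRecord, include_death: bool = True) -> bool:
    """True iff the patient hit the admission composite.

    The composite counts unplanned cardiovascular admissions, heart-failure
    admissions, and (by default) death; non-cardiovascular admissions and
    planned procedures never trigger it.
    """
    events = rec.unplanned_cv_admissions + rec.hf_admissions
    return events > 0 or (include_death and rec.died)


def readmission_flags(df: pd.DataFrame, include_death: bool = True) -> np.ndarray:
    """Vectorised admission-composite flag over a cohort frame."""
    flag = (df["unplanned_cv_admissions"] + df["hf_admissions"]) > 0
    if include_death:
        flag = flag | df["died"].astype(bool)
    return flag.to_numpy()


def classify_wrf(egfr0, egfr1, scr0, scr1, threshold: float = 0.25) -> bool:
    """Worsening renal function: eGFR fell by >= threshold, or SCr rose by >= threshold.

    Both timepoints of each analyte must share units; the classification is
    scale-invariant given that.
    """
    if egfr0 <= 0 or scr0 <= 0:
        raise ValidationError("baseline eGFR and SCr must be positive")
    return egfr1 <= (1 - threshold) * egfr0 or scr1 >= (1 + threshold) * scr0


def fta_flag(booked: int, attended: int) -> bool:
    """True iff strictly more than 25% of pre-booked appointments were missed."""
    if booked <= 0:
        raise ValidationError("FTA is undefined without booked appointments")
    if attended < 0 or attended > booked:
        raise ValidationError("attended must be in 0..booked")
    return (booked - attended) / booked > 0.25


def _band_label(k: int) -> str:
    for label, lo, hi in ADMISSION_BANDS:
        if k >= lo and (hi is None or k <= hi):
            return label
    raise AssertionError("bands partition the non-negative integers")


@dataclass(frozen=True)
class MACESummary:
    """Per-short-form-category 12-month event summary (Table-5 shaped)."""

    table: pd.DataFrame  # indexed by category 0-3
    band_counts: pd.Series = field(repr=False)  # cohort-wide admission bands
    n: int = 0


def mace_summary(df: pd.DataFrame, sf_source: str = "nurse", include_death: bool = True) -> MACESummary:
    """Summarise 12-month events by short-form category.

    For each category: patient count, admission-composite events and rate,
    deaths, loss to follow-up, mean total admissions, FTA rate, side-effect
    count; plus cohort-wide admission-count bands (0 / 1 / 2-3 / 4+) over
    all admissions (cardiac and non-cardiac).
    """
    if len(df) == 0:
        raise ValidationError("empty cohort")
    work = df.copy()
    work["sf_cat"] = sf_categories(df, source=sf_source)
    work["event"] = readmission_flags(df, include_death=include_death)
    work["all_adm"] = (
        work["unplanned_cv_admissions"] + work["hf_admissions"] + work["non_cv_admissions"]
    )
    booked = work["booked_appointments"]
    missed_frac = np.where(booked > 0, (booked - work["attended_appointments"]) / booked.replace(0, 1), np.nan)
    work["fta"] = missed_frac > 0.25
    work["side_effect"] = (
        work["dose_reduced"].astype(bool) | work["dose_ceased"].astype(bool) | work["wrf"].astype(bool)
    )

    rows = []
    for cat in range(4):
        g = work[work["sf_cat"] == cat]
        rows.append(
            {
                "category": cat,
                "n": len(g),
                "events": int(g["event"].sum()),
                "event_rate": float(g["event"].mean()) if len(g) else np.nan,
                "deaths": int(g["died"].sum()),
                "ltfu": int(g["ltfu"].sum()),
                "mean_admissions": float(g["all_adm"].mean()) if len(g) else np.nan,
                "fta_rate": float(g["fta"].mean()) if len(g) else np.nan,
                "side_effects": int(g["side_effect"].sum()),
            }
        )
    table = pd.DataFrame(rows).set_index("category")
    bands = work["all_adm"].map(_band_label)
    band_counts = bands.value_counts().reindex([b[0] for b in ADMISSION_BANDS], fill_value=0)
    return MACESummary(table=table, band_counts=band_counts, n=len(work))
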