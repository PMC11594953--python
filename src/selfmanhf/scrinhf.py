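"""The SCRinHF short form: three binary self-management domains.

A nurse scores three domains in a binary fashion -- self-maintenance (Ma),
self-management/tailoring (Mx) and self-efficacy (Mse) -- with 0 meaning
competent and 1 meaning poor.  The domain sum (0-3) is itself the ordinal
risk category: 0 good, 1 average, 2 borderline, 3 poor.

The short-form domains shadow long-form composites: Ma covers knowledge plus
coping (KC), Mx covers partnership plus symptom management (PM), and Mse
covers the whole instrument.  A long-form score therefore induces a
*derived* short-form assessment through pass thresholds at half of each
composite scale, applied strictly (a score of exactly half fails).  Two
mapping variants exist:

``composite`` (default)
    pass on the composite sum: Ma passes iff KC > 24, Mx iff PM > 24,
    Mse iff total > 48.
``conjunctive``
    pass only if every member domain passes its own half-scale threshold:
    Ma iff K > 8 and C > 16; Mx iff P > 16 and M > 8; Mse iff total > 48.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .instruments import Category, DomainScores


@dataclass(frozen=True)
class SFAssessment:
    """One short-form assessment: three binary domains, 0 = pass/competent."""

    ma: int
    mx: int
    mse: int

    def __post_init__(self):
        for name in ("ma", "mx", "mse"):
            v = getattr(self, name)
            if isinstance(v, bool) or v not in (0, 1):
                raise ValidationError(f"SF domain {name} must be 0 or 1, got {v!r}")

    @property
    def total(self) -> int:
        return self.ma + self.mx + self.mse

    @property
    def category(self) -> Category:
        return Category(self.total)


@dataclass(frozen=True)
class PassThresholds:
    """Strict ('>') pass thresholds at half of each scale maximum."""

    domain_16_pass: int = 8
    domain_32_pass: int = 16
    composite_48_pass: int = 24
    total_pass: int = 48


DEFAULT_THRESHOLDS = PassThresholds()


def sf_total(assessment: SFAssessment) -> Category:
    """The short-form category: the sum of the three binary domains."""
    return assessment.category


def lf_to_sf_equivalent(
    scores: DomainScores,
    thresholds: PassThresholds = DEFAULT_THRESHOLDS,
    mapping: str = "composite",
) -> SFAssessment:
    """Derive the short-form assessment a long-form score implies.

    Each domain scores 0 (pass) when the corresponding long-form quantity
    strictly exceeds its half-scale threshold, else 1.
    """
    if mapping == "composite":
        ma = 0 if scores.kc > thresholds.composite_48_pass else 1
        mx = 0 if scores.pm > thresholds.composite_48_pass else 1
    elif mapping == "conjunctive":
        ma = 0 if (scores.k > thresholds.domain_16_pass and scores.c > thresholds.domain_32_pass) else 1
        mx = 0 if (scores.p > thresholds.domain_32_pass and scores.m > thresholds.domain_16_pass) else 1
    else:
        raise ValidationError(f"unknown sf mapping {mapping!r}; use 'composite' or 'conjunctive'")
    mse = 0 if scores.total > thresholds.total_pass else 1
    return SFAssessment(ma=ma, mx=mx, mse=mse)


def sf_categories(df, source: str = "nurse", mapping: str = "composite") -> np.ndarray:
    """Per-patient short-form category over a cohort frame.

    ``source='nurse'`` sums the recorded ``sf_ma``/``sf_mx``/``sf_mse``
    columns; ``source='derived'`` recomputes the assessment from the PIH
    items via :func:`lf_to_sf_equivalent`.
    """
    if source == "nurse":
        for col in ("sf_ma", "sf_mx", "sf_mse"):
            bad = ~df[col].isin([0, 1])
            if bad.any():
                row = int(df.index[bad][0])
                raise ValidationError(f"{col} not binary at row {row}")
        return (df["sf_ma"] + df["sf_mx"] + df["sf_mse"]).to_numpy(dtype=int)
    if source == "derived":
        items = df[[f"pih_item_{i}" for i in range(1, 13)]].to_numpy(dtype=int)
        k = items[:, 0:2].sum(axis=1)
        p = items[:, 2:6].sum(axis=1)
        m = items[:, 6:8].sum(axis=1)
        c = items[:, 8:12].sum(axis=1)
        th = DEFAULT_THRESHOLDS
        if mapping == "composite":
            ma = np.where(k + c > th.composite_48_pass, 0, 1)
            mx = np.where(p + m > th.composite_48_pass, 0, 1)
        elif mapping == "conjunctive":
            ma = np.where((k > th.domain_16_pass) & (c > th.domain_32_pass), 0, 1)
            mx = np.where((p > th.domain_32_pass) & (m > th.domain_16_pass), 0, 1)
        else:
            raise ValidationError(f"unknown sf mapping {mapping!r}")
        mse = np.where(k + p + m + c > th.total_pass, 0, 1)
        return (ma + mx + mse).astype(int)
    raise ValidationError(f"unknown SF source {source!r}; use 'nurse' or 'derived'")
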