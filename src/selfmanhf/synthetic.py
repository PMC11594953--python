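"""Synthetic heart-failure cohorts with the structure the analyses assume.

One latent self-management trait per patient drives everything observed:

* the 12 PIH items are ``clamp(round(4 + loading * z + noise), 0, 8)`` --
  a single-factor model with independent Gaussian item noise;
* the nurse's short-form assessment is the long-form-derived equivalent
  with each binary domain flipped independently with probability
  ``nurse_flip_prob`` (emulating rater misclassification);
* 12-month outcomes are drawn from category-conditional distributions,
  conditioned on the nurse short-form category.  Death is a sub-event of
  the admission composite, so a death always registers as a composite
  event and the category-conditional composite rate equals
  ``admission_prob_by_category`` exactly in expectation.

Default parameters are fixed at the study's marginals: n=117, age 66.8
(SD 13.5), 75% male, composite event probability 5/13 for good and 31/38
for poor self-managers (intermediate categories linearly interpolated),
death probability 0 for good and 4/38 for poor.

``calibrate_to_margins`` inverts latent-normal quantiles so the expected
short-form category proportions hit target counts; a calibrated parameter
set assigns nurse categories directly from the trait thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ValidationError
from .instruments import score_pih
from .scrinhf import lf_to_sf_equivalent

# admission composite probabilities at the study's extreme-category rates,
# middle categories linearly interpolated (assumption; see docs/methods.md)
_P_GOOD = 5 / 13
_P_POOR = 31 / 38
_D_GOOD = 0.0
_D_POOR = 4 / 38


def _interp4(lo: float, hi: float) -> tuple[float, float, float, float]:
    return tuple(lo + (hi - lo) * k / 3 for k in range(4))


# nurse SF domain pattern per directly-assigned category total;
# self-efficacy (the most stringent domain) fails first, then
# self-maintenance, then self-tailoring
_DOMAINS_OF_TOTAL = {0: (0, 0, 0), 1: (0, 0, 1), 2: (1, 0, 1), 3: (1, 1, 1)}


@dataclass(frozen=True)
class CohortParams:
    """Generator parameters; defaults emulate the study cohort."""

    n: int = 117
    seed: int = 0
    trait_sd: float = 1.0
    item_loading: float = 1.0
    item_noise_sd: float = 1.5
    nurse_flip_prob: float = 0.1
    admission_prob_by_category: tuple[float, float, float, float] = _interp4(_P_GOOD, _P_POOR)
    death_prob_by_category: tuple[float, float, float, float] = _interp4(_D_GOOD, _D_POOR)
    extra_admission_rate: float = 1.0
    ltfu_prob: float = 9 / 117
    age_mean: float = 66.8
    age_sd: float = 13.5
    male_fraction: float = 0.75
    # probability of comorbidity-count band: 0, 1-3, 4-6, 7-8
    comorbidity_band_probs: tuple[float, float, float, float] = (30 / 117, 26 / 117, 59 / 117, 2 / 117)
    hf_admission_fraction: float = 0.45
    non_cv_admission_rate: float = 0.4
    planned_procedure_rate: float = 0.3
    # failure-to-attend miss probability per appointment, good -> poor
    miss_prob_by_category: tuple[float, float, float, float] = _interp4(0.12, 0.32)
    booked_mean: float = 20.0
    # latent-trait thresholds from calibrate_to_margins; when set, nurse SF
    # categories come directly from the trait rather than the derived+flip path
    trait_thresholds: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.n <= 0:
            raise ValidationError("cohort size n must be positive")
        if not 0 <= self.nurse_flip_prob <= 1:
            raise ValidationError("nurse_flip_prob must be in [0, 1]")
        for name in ("admission_prob_by_category", "death_prob_by_category", "miss_prob_by_category"):
            probs = getattr(self, name)
            if len(probs) != 4 or any(not 0 <= p <= 1 for p in probs):
                raise ValidationError(f"{name} must be four probabilities in [0, 1]")
        if any(d > a for d, a in zip(self.death_prob_by_category, self.admission_prob_by_category)):
            raise ValidationError("death probability may not exceed the composite event probability")
        if not np.isclose(sum(self.comorbidity_band_probs), 1.0):
            raise ValidationError("comorbidity band probabilities must sum to 1")


_COMORBIDITY_BANDS = [(0, 0), (1, 3), (4, 6), (7, 8)]


def _one_patient(pid: int, params: CohortParams, rng: np.random.Generator) -> dict:
    z = rng.normal(0.0, params.trait_sd)
    noise = rng.normal(0.0, params.item_noise_sd, size=12)
    items = np.clip(np.rint(4.0 + params.item_loading * z + noise), 0, 8).astype(int)
    scores = score_pih(items)
    derived = lf_to_sf_equivalent(scores)

    if params.trait_thresholds is not None:
        # calibrated mode: category straight from the trait (low z = high risk)
        cat = 3 - int(np.searchsorted(np.asarray(params.trait_thresholds), z, side="right"))
        ma, mx, mse = _DOMAINS_OF_TOTAL[cat]
    else:
        flips = rng.random(3) < params.nurse_flip_prob
        ma = int(derived.ma) ^ int(flips[0])
        mx = int(derived.mx) ^ int(flips[1])
        mse = int(derived.mse) ^ int(flips[2])
        cat = ma + mx + mse

    # outcomes conditional on the nurse category
    p_event = params.admission_prob_by_category[cat]
    p_death = params.death_prob_by_category[cat]
    event = rng.random() < p_event
    died = bool(event and p_event > 0 and rng.random() < p_death / p_event)
    if event:
        composite_adm = int(rng.poisson(params.extra_admission_rate))
        if not died:
            composite_adm += 1  # survivors need an admission to register the event
    else:
        composite_adm = 0
    hf_adm = int(rng.binomial(composite_adm, params.hf_admission_fraction)) if composite_adm else 0
    cv_adm = composite_adm - hf_adm
    non_cv = int(rng.poisson(params.non_cv_admission_rate))
    planned = int(rng.poisson(params.planned_procedure_rate))

    ltfu = bool((not died) and rng.random() < params.ltfu_prob)
    follow_up = 12 if not (died or ltfu) else int(rng.integers(1, 12))

    booked = 1 + int(rng.poisson(params.booked_mean))
    attended = booked - int(rng.binomial(booked, params.miss_prob_by_category[cat]))

    egfr0 = float(np.clip(rng.normal(62.0, 18.0), 15.0, 120.0))
    egfr1 = float(np.clip(egfr0 * (1.0 - rng.normal(0.05, 0.12)), 5.0, 130.0))
    scr0 = float(np.clip(rng.normal(95.0, 25.0), 40.0, 300.0))
    scr1 = float(np.clip(scr0 * (1.0 + rng.normal(0.05, 0.12)), 30.0, 500.0))
    wrf = egfr1 <= 0.75 * egfr0 or scr1 >= 1.25 * scr0

    band = _COMORBIDITY_BANDS[int(rng.choice(4, p=params.comorbidity_band_probs))]
    comorbidity = int(rng.integers(band[0], band[1] + 1))

    rec = {
        "patient_id": pid,
        "age": round(float(np.clip(rng.normal(params.age_mean, params.age_sd), 18, 100)), 1),
        "sex": "M" if rng.random() < params.male_fraction else "F",
        "comorbidity_count": comorbidity,
        **{f"pih_item_{i + 1}": int(items[i]) for i in range(12)},
        "sf_ma": ma,
        "sf_mx": mx,
        "sf_mse": mse,
        "unplanned_cv_admissions": cv_adm,
        "hf_admissions": hf_adm,
        "non_cv_admissions": non_cv,
        "planned_procedures": planned,
        "died": int(died),
        "ltfu": int(ltfu),
        "follow_up_months": follow_up,
        "booked_appointments": booked,
        "attended_appointments": attended,
        "dose_reduced": int(rng.random() < 0.15),
        "dose_ceased": int(rng.random() < 0.08),
        "wrf": int(wrf),
        "egfr_baseline": round(egfr0, 2),
        "egfr_followup": round(egfr1, 2),
        "scr_baseline": round(scr0, 2),
        "scr_followup": round(scr1, 2),
        "latent_trait": round(float(z), 4),
    }
    return rec


def generate_cohort(params: CohortParams | None = None, **overrides) -> pd.DataFrame:
    """Generate a cohort frame, deterministic under a fixed seed.

    Each patient draws from an independent substream spawned from the master
    seed, so cohorts are reproducible under partial regeneration.
    """
    if params is None:
        params = CohortParams(**overrides)
    elif overrides:
        params = replace(params, **overrides)
    children = np.random.SeedSequence(params.seed).spawn(params.n)
    rows = [
        _one_patient(pid, params, np.random.default_rng(child))
        for pid, child in enumerate(children)
    ]
    return pd.DataFrame(rows)


def calibrate_to_margins(target_counts, n: int, params: CohortParams | None = None) -> CohortParams:
    """Fit latent-trait thresholds so expected SF category proportions match targets.

    ``target_counts`` are the four category counts (good..poor) summing to
    ``n``.  Thresholds are latent-normal quantiles: with targets p0..p3 the
    cut points sit at the cumulative poor-to-good quantiles of
    Normal(0, trait_sd).  Returns a parameter set with ``trait_thresholds``
    populated; degenerate (zero-count) categories get infinite thresholds.
    """
    params = params or CohortParams(n=n)
    counts = np.asarray(target_counts, dtype=float)
    if counts.size != 4 or (counts < 0).any():
        raise ValidationError("need four non-negative category counts")
    if n <= 0 or counts.sum() != n:
        raise ValidationError(f"target counts sum to {counts.sum():g}, expected n={n}")
    props = counts / n
    # cumulative mass from the poor end of the trait axis upward
    cum = np.cumsum(props[::-1])[:3]  # P(poor), P(poor|bl), P(poor|bl|avg)
    thresholds = tuple(float(norm.ppf(c, scale=params.trait_sd)) for c in cum)
    return replace(params, n=n, trait_thresholds=thresholds)


def expected_category_proportions(params: CohortParams) -> np.ndarray:
    """Expected SF category proportions (good..poor) under calibrated thresholds."""
    if params.trait_thresholds is None:
        raise ValidationError("parameters carry no trait thresholds; run calibrate_to_margins")
    cdf = np.array([0.0, *[norm.cdf(t, scale=params.trait_sd) for t in params.trait_thresholds], 1.0])
    if np.any(np.diff(cdf) < -1e-12):
        raise ValidationError("thresholds must be non-decreasing")
    poor_to_good = np.diff(cdf)  # P(poor), P(borderline), P(average), P(good)
    return poor_to_good[::-1]
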