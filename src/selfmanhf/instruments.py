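"""Scoring and categorical banding of the Partners in Health (PIH) long form.

The PIH is a 12-item patient-reported instrument; each item is answered on a
0-8 Likert scale (0 = worst, 8 = best).  Items aggregate into four domains --
Knowledge (K, items 1-2, max 16), Partnership in treatment (P, items 3-6,
max 32), symptom recognition/Management (M, items 7-8, max 16) and Coping
(C, items 9-12, max 32) -- plus the composites KC = K + C, PM = P + M (max 48
each) and the 96-point total.

Every scale is banded into four ordinal self-management categories (good <
average < borderline < poor, coded 0-3 in increasing risk) by scale-specific
integer cut-offs.  The cut-off tables are data, not code: they live in
``data/banding.yaml`` and are validated to partition the score range on load.
"""

from __future__ import annotations

import enum
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from importlib import resources
from functools import lru_cache

import numpy as np
import yaml

from .errors import ValidationError

N_ITEMS = 12
ITEM_MIN, ITEM_MAX = 0, 8

# item index ranges (1-based, inclusive) per domain
_DOMAIN_ITEMS = {"K": (1, 2), "P": (3, 6), "M": (7, 8), "C": (9, 12)}


class Category(enum.IntEnum):
    """Ordinal self-management category; the code doubles as a risk rank."""

    GOOD = 0
    AVERAGE = 1
    BORDERLINE = 2
    POOR = 3

    @property
    def label(self) -> str:
        return self.name.lower()


@dataclass(frozen=True)
class DomainScores:
    """Aggregated long-form domain scores.

    Attributes
    ----------
    k, p, m, c
        Domain subtotals: knowledge (0-16), partnership (0-32), symptom
        management (0-16), coping (0-32).
    """

    k: int
    p: int
    m: int
    c: int

    def __post_init__(self):
        bounds = {"k": 16, "p": 32, "m": 16, "c": 32}
        for name, hi in bounds.items():
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ValidationError(f"domain {name.upper()} must be an integer, got {v!r}")
            if not 0 <= v <= hi:
                raise ValidationError(f"domain {name.upper()}={v} outside [0, {hi}]")

    @property
    def kc(self) -> int:
        return self.k + self.c

    @property
    def pm(self) -> int:
        return self.p + self.m

    @property
    def total(self) -> int:
        return self.k + self.p + self.m + self.c


def _coerce_items(responses) -> list[int]:
    """Normalise a response vector to a 12-long list, validating as we go."""
    if isinstance(responses, Mapping):
        seq = [responses.get(i, None) for i in range(1, N_ITEMS + 1)]
        extra = set(responses) - set(range(1, N_ITEMS + 1))
        if extra:
            raise ValidationError(f"unexpected item keys {sorted(extra)}; expected 1..{N_ITEMS}")
    else:
        seq = list(responses)
    if len(seq) != N_ITEMS:
        raise ValidationError(f"expected {N_ITEMS} item responses, got {len(seq)}")
    out = []
    for i, v in enumerate(seq, start=1):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValidationError(f"item_{i} is missing; missing responses are not imputed")
        if isinstance(v, bool) or not isinstance(v, (int, np.integer)):
            if isinstance(v, (float, np.floating)) and float(v).is_integer():
                v = int(v)
            else:
                raise ValidationError(f"item_{i}={v!r} is not an integer")
        v = int(v)
        if not ITEM_MIN <= v <= ITEM_MAX:
            raise ValidationError(f"item_{i}={v} outside Likert range [{ITEM_MIN}, {ITEM_MAX}]")
        out.append(v)
    return out


def score_pih(responses: Sequence[int] | Mapping[int, int]) -> DomainScores:
    """Score the 12 PIH item responses into domain subtotals.

    Parameters
    ----------
    responses
        The 12 Likert responses, as a sequence (item 1 first) or a mapping
        keyed by item number 1-12.  Every item must be present and in 0-8;
        missing or out-of-range values raise :class:`ValidationError` naming
        the offending item.
    """
    items = _coerce_items(responses)
    sums = {
        d: sum(items[lo - 1 : hi]) for d, (lo, hi) in _DOMAIN_ITEMS.items()
    }
    return DomainScores(k=sums["K"], p=sums["P"], m=sums["M"], c=sums["C"])


@dataclass(frozen=True)
class BandingScheme:
    """Four disjoint closed integer intervals partitioning [0, scale_max].

    ``bounds`` maps each :class:`Category` to its ``(lo, hi)`` interval.
    Construction validates the partition and the monotone ordering
    (every good score > every average score > ... > every poor score).
    """

    scale_max: int
    bounds: Mapping[Category, tuple[int, int]]

    def __post_init__(self):
        if set(self.bounds) != set(Category):
            raise ValidationError("a banding scheme needs all four categories")
        covered = np.zeros(self.scale_max + 1, dtype=int)
        for cat, (lo, hi) in self.bounds.items():
            if not (0 <= lo <= hi <= self.scale_max):
                raise ValidationError(
                    f"{cat.label} interval [{lo}, {hi}] outside [0, {self.scale_max}]"
                )
            covered[lo : hi + 1] += 1
        if not np.all(covered == 1):
            bad = int(np.flatnonzero(covered != 1)[0])
            raise ValidationError(
                f"score {bad} covered {covered[bad]} times; intervals must partition the range"
            )
        # increasing category code must mean strictly lower scores
        ordered = sorted(self.bounds.items(), key=lambda kv: kv[0])
        for (c_hi, (lo_hi, _)), (c_lo, (_, hi_lo)) in zip(ordered, ordered[1:]):
            if hi_lo >= lo_hi:
                raise ValidationError(
                    f"{c_lo.label} scores overlap or exceed {c_hi.label} scores"
                )

    def band(self, score: int) -> Category:
        return band_score(score, self)


@lru_cache(maxsize=1)
def default_schemes() -> dict[int, BandingScheme]:
    """The packaged cut-off tables, keyed by scale maximum (16/32/48/96)."""
    text = resources.files("selfmanhf.data").joinpath("banding.yaml").read_text()
    return load_schemes(yaml.safe_load(text))


def load_schemes(config: Mapping) -> dict[int, BandingScheme]:
    """Build validated :class:`BandingScheme` objects from a config mapping."""
    out = {}
    for scale_max, table in config["schemes"].items():
        scale_max = int(scale_max)
        bounds = {
            Category[name.upper()]: (int(lo), int(hi)) for name, (lo, hi) in table.items()
        }
        out[scale_max] = BandingScheme(scale_max=scale_max, bounds=bounds)
    return out


def band_score(score: int, scheme: BandingScheme) -> Category:
    """Map one integer score to its unique self-management category."""
    if isinstance(score, bool) or not isinstance(score, (int, np.integer)):
        raise ValidationError(f"score must be an integer, got {score!r}")
    if not 0 <= score <= scheme.scale_max:
        raise ValidationError(f"score {score} outside [0, {scheme.scale_max}]")
    for cat, (lo, hi) in scheme.bounds.items():
        if lo <= score <= hi:
            return cat
    raise AssertionError("unreachable: scheme partitions the range")


def band_scores(scores, scheme: BandingScheme) -> np.ndarray:
    """Vectorised :func:`band_score` over an integer array."""
    arr = np.asarray(scores)
    if not np.issubdtype(arr.dtype, np.integer):
        if np.any(arr != np.floor(arr)):
            raise ValidationError("scores must be integers")
        arr = arr.astype(int)
    if arr.size and (arr.min() < 0 or arr.max() > scheme.scale_max):
        bad = arr[(arr < 0) | (arr > scheme.scale_max)][0]
        raise ValidationError(f"score {bad} outside [0, {scheme.scale_max}]")
    out = np.empty(arr.shape, dtype=int)
    for cat, (lo, hi) in scheme.bounds.items():
        out[(arr >= lo) & (arr <= hi)] = int(cat)
    return out


# scale used to band each long-form quantity
SCALE_OF = {"K": 16, "P": 32, "M": 16, "C": 32, "KC": 48, "PM": 48, "total": 96}


def categorize_lf(
    scores: DomainScores, schemes: Mapping[int, BandingScheme] | None = None
) -> dict[str, Category]:
    """Band every long-form scale of one patient.

    Returns categories for K, P, M, C, KC, PM and the 96-point total; the
    total-scale category is the long form's headline category.
    """
    schemes = schemes or default_schemes()
    values = {
        "K": scores.k,
        "P": scores.p,
        "M": scores.m,
        "C": scores.c,
        "KC": scores.kc,
        "PM": scores.pm,
        "total": scores.total,
    }
    return {name: band_score(v, schemes[SCALE_OF[name]]) for name, v in values.items()}
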