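"""Agreement between the short- and long-form categories, and the
category-outcome contingency statistics.

The study's primary endpoint is 80% concordance: the proportion of patients
assigned the same ordinal category by both instruments.  The headline
readmission analysis contrasts the extreme categories (good vs poor) on a
2x2 table of the admission composite, tested with the uncorrected Pearson
chi-square at one degree of freedom; a full-enumeration Fisher exact test is
provided as the small-cell companion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError
from .instruments import Category

N_CATEGORIES = 4


@dataclass(frozen=True)
class CrossTab4x4:
    """Joint category counts, rows = short form, columns = long form."""

    counts: np.ndarray  # (4, 4) non-negative ints

    def __post_init__(self):
        arr = np.asarray(self.counts, dtype=int)
        if arr.shape != (N_CATEGORIES, N_CATEGORIES) or (arr < 0).any():
            raise ValidationError("counts must be a non-negative 4x4 grid")
        object.__setattr__(self, "counts", arr)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def sf_margin(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def lf_margin(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class ConcordanceReport:
    exact_agreement: float
    extreme_agreement: float | None  # None when no patient is rated good/poor
    meets_primary_endpoint: bool
    n: int
    n_extreme: int


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a,b / c,d: rows are category groups, columns event yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if isinstance(v, bool) or not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"cell {name}={v!r} must be a non-negative integer")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float


def crosstab(sf, lf) -> CrossTab4x4:
    """Cross-tabulate per-patient short-form vs long-form categories."""
    sf = np.asarray(sf, dtype=int)
    lf = np.asarray(lf, dtype=int)
    if sf.size == 0 or lf.size == 0:
        raise ValidationError("category lists must be non-empty")
    if sf.shape != lf.shape:
        raise ValidationError(f"length mismatch: {sf.size} SF vs {lf.size} LF categories")
    for name, arr in (("SF", sf), ("LF", lf)):
        if arr.min() < 0 or arr.max() > 3:
            raise ValidationError(f"{name} categories must be in 0..3")
    counts = np.zeros((N_CATEGORIES, N_CATEGORIES), dtype=int)
    np.add.at(counts, (sf, lf), 1)
    return CrossTab4x4(counts=counts)


def concordance_proportion(tab: CrossTab4x4, threshold: float = 0.80) -> ConcordanceReport:
    """Exact and extreme-category agreement, with the primary-endpoint flag.

    ``exact_agreement`` is trace/n.  ``extreme_agreement`` restricts to
    patients whom either instrument rates good (0) or poor (3) and asks how
    often the instruments agree there.
    """
    if tab.n == 0:
        raise ValidationError("cannot compute agreement on an empty table")
    exact = float(np.trace(tab.counts)) / tab.n
    extreme_cats = (int(Category.GOOD), int(Category.POOR))
    mask = np.zeros_like(tab.counts, dtype=bool)
    mask[list(extreme_cats), :] = True
    mask[:, list(extreme_cats)] = True
    n_extreme = int(tab.counts[mask].sum())
    if n_extreme:
        agree_extreme = sum(int(tab.counts[k, k]) for k in extreme_cats)
        extreme = agree_extreme / n_extreme
    else:
        extreme = None
    return ConcordanceReport(
        exact_agreement=exact,
        extreme_agreement=extreme,
        meets_primary_endpoint=exact >= threshold,
        n=tab.n,
        n_extreme=n_extreme,
    )


def pearson_chi2_2x2(tab: ContingencyTable2x2, correction: bool = False) -> Chi2Result:
    """Pearson chi-square on a 2x2 table, uncorrected by default.

    Uses the closed form n(ad - bc)^2 / (r1 r2 c1 c2); with ``correction``
    the Yates continuity-corrected version substitutes
    (|ad - bc| - n/2)^2, floored at zero.  One degree of freedom.
    """
    a, b, c, d = tab.a, tab.b, tab.c, tab.d
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValidationError(
            "a row or column margin is zero; the chi-square test is undefined -- "
            "use exact_test_2x2 instead"
        )
    cross = a * d - b * c
    if correction:
        num = max(abs(cross) - n / 2.0, 0.0) ** 2
    else:
        num = float(cross) ** 2
    statistic = n * num / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(statistic, df=1))
    return Chi2Result(statistic=float(statistic), df=1, p_value=p)


def exact_test_2x2(tab: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by full enumeration with fixed margins.

    Enumerates every table compatible with the observed margins and sums the
    hypergeometric probabilities of tables no more probable than the
    observed one (with a small relative tolerance against float noise).
    """
    a, b, c, d = tab.a, tab.b, tab.c, tab.d
    n = a + b + c + d
    if n == 0:
        raise ValidationError("empty table")
    r1, c1 = a + b, a + c
    # a ~ Hypergeometric(n, c1, r1) under the null of independence
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    dist = stats.hypergeom(n, c1, r1)
    p_obs = dist.pmf(a)
    support = np.arange(lo, hi + 1)
    pmf = dist.pmf(support)
    p = float(pmf[pmf <= p_obs * (1 + 1e-10)].sum())
    return min(p, 1.0)


@dataclass(frozen=True)
class DistributionStats:
    mean: float
    sd: float
    range: tuple[int, int]
    n: int


def category_distribution_stats(counts) -> DistributionStats:
    """Mean, sample SD and observed range of the score list a count vector implies.

    ``counts[k]`` is the number of patients with score ``k``; the SD uses the
    n-1 denominator.  The range spans the lowest to highest score with
    non-zero count.
    """
    counts = np.asarray(counts, dtype=int)
    if (counts < 0).any():
        raise ValidationError("counts must be non-negative")
    n = int(counts.sum())
    if n == 0:
        raise ValidationError("counts sum to zero")
    scores = np.arange(counts.size)
    mean = float(np.dot(counts, scores)) / n
    if n > 1:
        ss = float(np.dot(counts, (scores - mean) ** 2))
        sd = float(np.sqrt(ss / (n - 1)))
    else:
        sd = 0.0
    nz = np.flatnonzero(counts)
    return DistributionStats(mean=mean, sd=sd, range=(int(nz[0]), int(nz[-1])), n=n)
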