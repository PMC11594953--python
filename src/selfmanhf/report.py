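"""Render the study-shaped analysis report from a cohort frame.

Produces a banding/distribution table (one block per long-form scale plus
the short form), an outcome table by short-form category, and the
concordance and chi-square headline results, as plain text and as
DataFrames ready for CSV export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .concordance import (
    Chi2Result,
    ConcordanceReport,
    ContingencyTable2x2,
    category_distribution_stats,
    concordance_proportion,
    crosstab,
    pearson_chi2_2x2,
)
from .errors import ValidationError
from .instruments import SCALE_OF, band_scores, default_schemes
from .outcomes import MACESummary, mace_summary, readmission_flags
from .scrinhf import sf_categories

log = logging.getLogger(__name__)

_DOMAIN_ITEM_SLICES = {"K": (0, 2), "P": (2, 6), "M": (6, 8), "C": (8, 12)}


def lf_scale_scores(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-patient scores for every long-form scale (K/P/M/C/KC/PM/total)."""
    items = df[[f"pih_item_{i}" for i in range(1, 13)]].to_numpy(dtype=int)
    out = {d: items[:, lo:hi].sum(axis=1) for d, (lo, hi) in _DOMAIN_ITEM_SLICES.items()}
    out["KC"] = out["K"] + out["C"]
    out["PM"] = out["P"] + out["M"]
    out["total"] = items.sum(axis=1)
    return out


def banding_table(df: pd.DataFrame, sf_source: str = "nurse") -> pd.DataFrame:
    """Category counts, %, and score mean/SD/range per scale, plus the SF row."""
    schemes = default_schemes()
    n = len(df)
    rows = []
    scales = lf_scale_scores(df)
    for name, scores in scales.items():
        cats = band_scores(scores, schemes[SCALE_OF[name]])
        for cat in range(4):
            count = int((cats == cat).sum())
            rows.append(
                {
                    "scale": name,
                    "category": cat,
                    "n": count,
                    "pct": 100.0 * count / n,
                    "mean": float(scores.mean()) if cat == 0 else np.nan,
                    "sd": float(scores.std(ddof=1)) if cat == 0 and n > 1 else np.nan,
                    "min": int(scores.min()) if cat == 0 else np.nan,
                    "max": int(scores.max()) if cat == 0 else np.nan,
                }
            )
    sf = sf_categories(df, source=sf_source)
    sf_counts = np.bincount(sf, minlength=4)
    sf_stats = category_distribution_stats(sf_counts)
    for cat in range(4):
        rows.append(
            {
                "scale": "SF",
                "category": cat,
                "n": int(sf_counts[cat]),
                "pct": 100.0 * sf_counts[cat] / n,
                "mean": sf_stats.mean if cat == 0 else np.nan,
                "sd": sf_stats.sd if cat == 0 else np.nan,
                "min": sf_stats.range[0] if cat == 0 else np.nan,
                "max": sf_stats.range[1] if cat == 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def extreme_category_table(df: pd.DataFrame, sf_source: str = "nurse") -> ContingencyTable2x2:
    """The good-vs-poor 2x2 of the admission composite."""
    sf = sf_categories(df, source=sf_source)
    event = readmission_flags(df)
    good, poor = sf == 0, sf == 3
    return ContingencyTable2x2(
        a=int((good & event).sum()),
        b=int((good & ~event).sum()),
        c=int((poor & event).sum()),
        d=int((poor & ~event).sum()),
    )


@dataclass(frozen=True)
class AnalysisReport:
    banding: pd.DataFrame
    crosstab: pd.DataFrame
    concordance: ConcordanceReport
    readmission_table: ContingencyTable2x2
    chi2: Chi2Result | None
    mace: MACESummary
    alpha: float
    text: str


def render_report(df: pd.DataFrame, sf_source: str = "nurse", alpha: float = 0.01) -> AnalysisReport:
    """Run the full analysis on a cohort frame and render it.

    Returns the component tables plus a formatted text report.  The
    chi-square section is omitted (None) when a margin of the good-vs-poor
    table is empty.
    """
    if len(df) == 0:
        raise ValidationError("empty cohort")
    n = len(df)
    log.info("report: %d records in", n)
    banding = banding_table(df, sf_source=sf_source)
    schemes = default_schemes()
    sf = sf_categories(df, source=sf_source)
    lf = band_scores(lf_scale_scores(df)["total"], schemes[96])
    tab = crosstab(sf, lf)
    conc = concordance_proportion(tab)
    ct = extreme_category_table(df, sf_source=sf_source)
    try:
        chi2 = pearson_chi2_2x2(ct)
    except ValidationError:
        chi2 = None
    mace = mace_summary(df, sf_source=sf_source)
    log.info(
        "report: categories assigned (SF good..poor = %s), %d composite events",
        np.bincount(sf, minlength=4).tolist(),
        int(readmission_flags(df).sum()),
    )

    lines = [f"Self-management analysis report (n={n}, SF source: {sf_source})", ""]
    lines.append("Category distribution by scale (category 0 good .. 3 poor):")
    for scale in banding["scale"].unique():
        block = banding[banding["scale"] == scale]
        head = block.iloc[0]
        counts = "  ".join(f"{int(r.category)}: {int(r.n)} ({r.pct:.1f}%)" for r in block.itertuples())
        lines.append(
            f"  {scale:>5}: {counts}   mean {head['mean']:.2f}  SD {head['sd']:.2f}  "
            f"range {int(head['min'])}-{int(head['max'])}"
        )
    lines.append("")
    lines.append("SF x LF cross-tabulation (rows SF, columns LF):")
    for i in range(4):
        lines.append("    " + "  ".join(f"{tab.counts[i, j]:4d}" for j in range(4)))
    lines.append(
        f"Exact agreement: {conc.exact_agreement:.3f} "
        f"(primary endpoint >= 0.80: {'MET' if conc.meets_primary_endpoint else 'NOT MET'})"
    )
    if conc.extreme_agreement is not None:
        lines.append(
            f"Extreme-category agreement (good/poor, n={conc.n_extreme}): {conc.extreme_agreement:.3f}"
        )
    lines.append("")
    lines.append(
        f"Admission composite, good vs poor: {ct.a}/{ct.a + ct.b} vs {ct.c}/{ct.c + ct.d}"
    )
    if chi2 is not None:
        decision = "associated" if chi2.p_value < alpha else "not associated"
        lines.append(
            f"Pearson chi-square = {chi2.statistic:.3f} at {chi2.df} degree of freedom, "
            f"p = {chi2.p_value:.4f} ({decision} at alpha={alpha:g})"
        )
    else:
        lines.append("Chi-square unavailable (empty margin); use the exact test.")
    lines.append("")
    lines.append("Outcomes by SF category:")
    lines.append(mace.table.to_string(float_format=lambda v: f"{v:.3f}"))
    lines.append("Admission-count bands: " + "  ".join(f"{k}: {v}" for k, v in mace.band_counts.items()))

    xtab = pd.DataFrame(tab.counts, index=[f"sf_{i}" for i in range(4)], columns=[f"lf_{j}" for j in range(4)])
    return AnalysisReport(
        banding=banding,
        crosstab=xtab,
        concordance=conc,
        readmission_table=ct,
        chi2=chi2,
        mace=mace,
        alpha=alpha,
        text="\n".join(lines),
    )
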