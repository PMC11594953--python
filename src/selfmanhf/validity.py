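"""Concurrent and predictive validity: linear association analyses.

Concurrent validity regresses the long-form total on the short-form total,
adjusting for age, sex and comorbidity count; the short-form coefficient is
the headline association.  Predictive validity fits the 12-month event count
on the same predictors.  Both use ordinary least squares with conventional
(homoskedastic) standard errors, two-sided p values, and 95% confidence
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ValidationError
from .scrinhf import sf_categories


@dataclass(frozen=True)
class LinearFit:
    """An OLS fit: coefficient table plus basic fit metadata."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame  # columns 'lower', 'upper' (95%)
    nobs: int
    df_resid: int
    resid_var: float

    def summary_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
                "ci_lower": self.conf_int["lower"],
                "ci_upper": self.conf_int["upper"],
            }
        )
        return out


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < X.shape[1]:
        # name a column whose removal restores full rank
        for col in X.columns:
            reduced = X.drop(columns=[col]).to_numpy(dtype=float)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValidationError(f"design matrix is rank deficient; column {col!r} is collinear")
        raise ValidationError("design matrix is rank deficient")


def linear_fit(y, X: pd.DataFrame, add_intercept: bool = True) -> LinearFit:
    """Ordinary least squares of ``y`` on the columns of ``X``.

    Requires a full-rank design and more observations than coefficients;
    a rank-deficient design raises naming the collinear column.
    """
    y = np.asarray(y, dtype=float)
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"x{i}" for i in range(X.shape[1])]
    if add_intercept and "const" not in X.columns:
        X = sm.add_constant(X, has_constant="add")
    if len(y) != len(X):
        raise ValidationError("outcome and design lengths differ")
    if len(y) <= X.shape[1]:
        raise ValidationError(f"need n > p: n={len(y)}, p={X.shape[1]}")
    _check_rank(X)
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    ci.columns = ["lower", "upper"]
    return LinearFit(
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        conf_int=ci,
        nobs=int(res.nobs),
        df_resid=int(res.df_resid),
        resid_var=float(res.scale),
    )


def _covariates(df: pd.DataFrame) -> pd.DataFrame:
    sex = df["sex"].map({"M": 1, "F": 0, 1: 1, 0: 0})
    if sex.isna().any():
        raise ValidationError("sex column must be 'M'/'F' (or 1/0)")
    return pd.DataFrame(
        {
            "age": df["age"].astype(float),
            "male": sex.astype(float),
            "comorbidity_count": df["comorbidity_count"].astype(float),
        },
        index=df.index,
    )


def lf_totals(df: pd.DataFrame) -> np.ndarray:
    """Per-patient 96-point long-form totals from the item columns."""
    items = df[[f"pih_item_{i}" for i in range(1, 13)]].to_numpy(dtype=int)
    return items.sum(axis=1)


def concurrent_validity(df: pd.DataFrame, sf_source: str = "nurse") -> LinearFit:
    """LF total ~ SF total + age + sex + comorbidity count."""
    X = _covariates(df)
    X.insert(0, "sf_total", sf_categories(df, source=sf_source).astype(float))
    return linear_fit(lf_totals(df), X)


def predictive_validity(df: pd.DataFrame, sf_source: str = "nurse") -> LinearFit:
    """12-month composite event count ~ SF total + age + sex + comorbidity count.

    The event count sums unplanned cardiovascular admissions, heart-failure
    admissions and death, fitted as a linear count model for transparency.
    """
    events = (
        df["unplanned_cv_admissions"].astype(int)
        + df["hf_admissions"].astype(int)
        + df["died"].astype(int)
    )
    X = _covariates(df)
    X.insert(0, "sf_total", sf_categories(df, source=sf_source).astype(float))
    return linear_fit(events.to_numpy(dtype=float), X)
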