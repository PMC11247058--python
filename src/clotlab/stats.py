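"""Summary statistics and least-squares regression tables.

Per-clot cohort tables are summarised as median [25th-75th percentile]
(the cellular contents are not normally distributed) and related to imaging
and mechanical outcomes by simple (one predictor) and multiple least-squares
linear regression, reported as unstandardised coefficients with t-based 95%
confidence intervals, two-sided p-values, the intercept and R². Fitting is
delegated to statsmodels OLS; this module owns the cohort-table schema.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionResult",
    "SummaryStats",
    "simple_ols",
    "multiple_ols",
    "median_iqr",
    "OUTCOME_PREDICTORS",
    "regression_tables",
]

#: significance threshold used when flagging coefficients
ALPHA = 0.05

#: model plan: outcome -> predictors of the multiple fit.
#: The CECT density increase additionally gets a (platelet, diameter) model
#: mirroring the clot-size analysis.
OUTCOME_PREDICTORS: Dict[str, Tuple[str, ...]] = {
    "ncct_density": ("rbc_content", "platelet_content"),
    "cect_increase": ("rbc_content", "platelet_content"),
    "low_stiffness": ("rbc_content", "platelet_content"),
    "high_stiffness": ("rbc_content", "platelet_content"),
    "hysteresis_loss": ("rbc_content", "platelet_content"),
    "plastic_strain": ("rbc_content", "platelet_content"),
}

#: supplementary size model for the contrast penetration outcome
SIZE_MODEL: Tuple[str, Tuple[str, ...]] = ("cect_increase", ("platelet_content", "diameter"))


@dataclass(frozen=True)
class SummaryStats:
    median: float
    iqr: Tuple[float, float]


@dataclass(frozen=True)
class RegressionResult:
    """Unstandardised OLS fit summary.

    ``beta``/``ci95``/``p_value`` are keyed by predictor name; the intercept
    is reported separately.
    """

    intercept: float
    beta: Dict[str, float]
    ci95: Dict[str, Tuple[float, float]]
    p_value: Dict[str, float]
    r_squared: float
    n: int
    intercept_ci95: Tuple[float, float] = (np.nan, np.nan)


def median_iqr(v: Sequence[float]) -> SummaryStats:
    """Median and 25th/75th percentiles (linear-interpolation convention)."""
    arr = np.asarray(v, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarise an empty vector")
    q25, q50, q75 = np.percentile(arr, [25, 50, 75])
    return SummaryStats(median=float(q50), iqr=(float(q25), float(q75)))


def _check_design(X: pd.DataFrame, n: int) -> None:
    p = X.shape[1]
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    const_cols = [c for c in X.columns if np.ptp(X[c].to_numpy()) == 0]
    if const_cols:
        raise ValueError(f"constant predictor column(s): {const_cols}")
    design = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # name the offending columns by testing each against the rest
        collinear = []
        for j, c in enumerate(X.columns):
            others = np.delete(design, j + 1, axis=1)
            proj, *_ = np.linalg.lstsq(others, design[:, j + 1], rcond=None)
            if np.allclose(others @ proj, design[:, j + 1]):
                collinear.append(c)
        raise ValueError(f"rank-deficient design; collinear column(s): {collinear}")


def multiple_ols(y: Sequence[float], X: pd.DataFrame, cov: str = "classical") -> RegressionResult:
    """Least-squares multiple linear regression with t-based 95% CIs.

    Degrees of freedom are n - p - 1; p-values are two-sided. With a single
    predictor column this reduces exactly to :func:`simple_ols`.
    ``cov="HC3"`` switches to heteroskedasticity-consistent standard errors
    (used when scoring recovery under multiplicative generative noise);
    the default matches the classical homoskedastic t intervals.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X)
    n = y.size
    if n != X.shape[0]:
        raise ValueError("y and X must have the same number of rows")
    _check_design(X, n)
    model = sm.OLS(y, sm.add_constant(X.astype(float), prepend=True))
    fit = model.fit() if cov == "classical" else model.fit(cov_type=cov)
    conf = fit.conf_int(alpha=0.05)
    names = list(X.columns)
    return RegressionResult(
        intercept=float(fit.params.iloc[0]),
        intercept_ci95=(float(conf.iloc[0, 0]), float(conf.iloc[0, 1])),
        beta={c: float(fit.params[c]) for c in names},
        ci95={c: (float(conf.loc[c, 0]), float(conf.loc[c, 1])) for c in names},
        p_value={c: float(fit.pvalues[c]) for c in names},
        r_squared=float(fit.rsquared),
        n=int(n),
    )


def simple_ols(y: Sequence[float], x: Sequence[float], name: str = "x") -> RegressionResult:
    """Simple (univariate) linear regression; CI with n - 2 df."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("simple_ols needs n >= 3")
    return multiple_ols(y, pd.DataFrame({name: x}))


def _rows_from_fit(outcome: str, kind: str, res: RegressionResult) -> List[dict]:
    rows = []
    for pred in res.beta:
        lo, hi = res.ci95[pred]
        rows.append(
            {
                "outcome": outcome,
                "model": kind,
                "predictor": pred,
                "beta": res.beta[pred],
                "ci_low": lo,
                "ci_high": hi,
                "p": res.p_value[pred],
                "r_squared": res.r_squared,
                "beta0": res.intercept,
                "n": res.n,
                "significant": res.p_value[pred] < ALPHA,
            }
        )
    return rows


def regression_tables(cohort: pd.DataFrame, include_size_model: bool = True) -> pd.DataFrame:
    """Simple and multiple regression rows for every outcome in the plan.

    ``cohort`` is a tidy per-clot table carrying at least rbc_content,
    platelet_content, diameter and whichever outcome columns are present;
    outcomes absent from the table are skipped. Returns one row per
    (outcome, model, predictor).
    """
    rows: List[dict] = []
    plans: List[Tuple[str, Tuple[str, ...], str]] = [
        (o, preds, "multiple") for o, preds in OUTCOME_PREDICTORS.items() if o in cohort.columns
    ]
    if include_size_model and SIZE_MODEL[0] in cohort.columns and "diameter" in cohort.columns:
        plans.append((SIZE_MODEL[0], SIZE_MODEL[1], "multiple_size"))
    for outcome, predictors, kind in plans:
        data = cohort.dropna(subset=[outcome, *predictors])
        y = data[outcome].to_numpy(dtype=float)
        if kind == "multiple":
            for pred in predictors:
                rows.extend(
                    _rows_from_fit(outcome, "simple", simple_ols(y, data[pred], name=pred))
                )
        rows.extend(_rows_from_fit(outcome, kind, multiple_ols(y, data[list(predictors)])))
    return pd.DataFrame(rows)
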