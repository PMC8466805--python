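"""Group descriptive statistics by enrollment status.

Replicates the study's descriptive table: per-variable treatment/control
means and SDs, a *control minus treatment* mean difference, and a Welch
two-sample t-test with significance stars.

Sign convention: the difference column is control mean minus treatment
mean.  This is the reverse of the common treatment-minus-control
convention but matches the published table's arithmetic (e.g. WHZ:
-0.376 - (-0.185) = -0.191).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: variables summarized when present, in display order
SUMMARY_VARIABLES = [
    "whz",
    "waz",
    "haz",
    "bmi",
    "outcome",
    "child_gender",
    "child_age",
    "mother_age",
    "mother_education",
    "log_income_pc",
    "living_area",
    "region",
]


def stars_from_p(p: float, thresholds: tuple[float, float, float] = (0.01, 0.05, 0.10)) -> str:
    """Significance stars: *** below 1%, ** below 5%, * below 10%."""
    if p < thresholds[0]:
        return "***"
    if p < thresholds[1]:
        return "**"
    if p < thresholds[2]:
        return "*"
    return ""


def mean_difference(treat_mean: float, control_mean: float) -> float:
    """Control-minus-treatment mean difference (published sign convention)."""
    if not (math.isfinite(treat_mean) and math.isfinite(control_mean)):
        raise ValueError("means must be finite")
    return control_mean - treat_mean


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    stars: str


def welch_t_test(x_values, y_values, pooled: bool = False) -> WelchResult:
    """Two-sample t-test, Welch (unequal variance) by default.

    Returns the t statistic, Satterthwaite degrees of freedom, two-sided p
    and significance stars at the 10/5/1% levels.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(x, y, equal_var=pooled)
    if pooled:
        df = float(len(x) + len(y) - 2)
    else:
        nx, ny = len(x), len(y)
        df = (vx / nx + vy / ny) ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
    t = float(res.statistic)
    p = float(res.pvalue)
    return WelchResult(t=t, df=float(df), p=p, stars=stars_from_p(p))


def summarize_by_group(
    dataset: pd.DataFrame,
    variables: list[str] | None = None,
    treatment_col: str = "treatment",
) -> pd.DataFrame:
    """Per-variable group summary with control-minus-treatment differences.

    Missing values are dropped per variable, so cohort-specific outcomes
    (z-scores only for ages 0-5, BMI only for 6-16) can live in one wide
    table.  Variables defaults to the intersection of
    :data:`SUMMARY_VARIABLES` with the dataset's columns.
    """
    W = dataset[treatment_col].to_numpy()
    if (W == 1).sum() < 2 or (W == 0).sum() < 2:
        raise ValueError("each arm needs at least 2 records")
    if variables is None:
        variables = [v for v in SUMMARY_VARIABLES if v in dataset.columns]
    rows = []
    for var in variables:
        col = dataset[var].astype(float)
        t_vals = col[W == 1].dropna().to_numpy()
        c_vals = col[W == 0].dropna().to_numpy()
        if len(t_vals) < 2 or len(c_vals) < 2:
            raise ValueError(f"variable {var!r} has fewer than 2 values in an arm")
        welch = welch_t_test(t_vals, c_vals)
        rows.append(
            {
                "variable": var,
                "treat_mean": t_vals.mean(),
                "treat_sd": t_vals.std(ddof=1),
                "control_mean": c_vals.mean(),
                "control_sd": c_vals.std(ddof=1),
                "difference": mean_difference(t_vals.mean(), c_vals.mean()),
                "t": welch.t,
                "p": welch.p,
                "stars": welch.stars,
            }
        )
    return pd.DataFrame(rows)
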