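"""Regression and ANCOVA comparison of CoT trends against reference data.

Predicted cost-of-transport values are regressed on a covariate (walking
speed or one of the asymmetry measures) and compared with reference
experimental points by analysis of covariance: the slope comparison is the
test of the covariate-by-group interaction in y ~ x * group, and the
intercept comparison is the test of the group effect in the common-slope
model y ~ x + group.  The absolute intercept difference is taken from the
two groups' separate fits.

Two subsetting rules accompany the comparison: reference points are
cropped to within 0.05 m/s of the predicted speed range, and
Fugl-Meyer-matched reference subjects are those within +/-3 points of the
study subject's score.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "TrendDataset",
    "AncovaResult",
    "fit_line",
    "ancova_compare",
    "crop_reference",
    "fm_subset",
]

COVARIATES = ("speed", "step_length_asym", "stance_time_asym", "double_support_asym")


@dataclass
class TrendDataset:
    """(covariate, CoT) points for one group."""

    x: np.ndarray
    y: np.ndarray  # CoT, J/(kg·m)
    group_label: str = "model_prediction"
    covariate_name: str = "speed"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same length")
        if self.x.size < 3:
            raise ValueError("need at least 3 points per group for regression")


@dataclass
class AncovaResult:
    slope_a: float
    slope_b: float
    intercept_a: float
    intercept_b: float
    p_slope: float  # interaction test (equal slopes)
    p_intercept: float  # group effect under a common slope
    abs_intercept_difference: float

    def __post_init__(self) -> None:
        for p in (self.p_slope, self.p_intercept):
            if not 0.0 <= p <= 1.0:
                raise ValueError("p-values must lie in [0, 1]")


def fit_line(x, y) -> tuple[float, float, float]:
    """OLS line fit: (slope, intercept, residual standard error)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0:
        raise ValueError("covariate has zero variance")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    dof = max(int(fit.df_resid), 1)
    se = float(np.sqrt(fit.ssr / dof))
    return float(fit.params[1]), float(fit.params[0]), se


def ancova_compare(a: TrendDataset, b: TrendDataset) -> AncovaResult:
    """ANCOVA slope and intercept comparison between two groups."""
    df = pd.DataFrame(
        {
            "x": np.concatenate([a.x, b.x]),
            "y": np.concatenate([a.y, b.y]),
            "group": ["a"] * a.x.size + ["b"] * b.x.size,
        }
    )
    slope_a, int_a, _ = fit_line(a.x, a.y)
    slope_b, int_b, _ = fit_line(b.x, b.y)
    with warnings.catch_warnings():
        # tiny perfectly-collinear fixtures trigger benign kurtosis warnings
        warnings.simplefilter("ignore")
        inter = smf.ols("y ~ x * C(group)", data=df).fit()
        common = smf.ols("y ~ x + C(group)", data=df).fit()
    p_slope = float(inter.pvalues["x:C(group)[T.b]"])
    p_intercept = float(common.pvalues["C(group)[T.b]"])
    if np.isnan(p_slope):  # identical groups: zero residual variance
        p_slope = 1.0
    if np.isnan(p_intercept):
        p_intercept = 1.0
    return AncovaResult(
        slope_a=slope_a,
        slope_b=slope_b,
        intercept_a=int_a,
        intercept_b=int_b,
        p_slope=p_slope,
        p_intercept=p_intercept,
        abs_intercept_difference=abs(int_a - int_b),
    )


def crop_reference(
    reference: pd.DataFrame, predicted_speeds, margin: float = 0.05
) -> pd.DataFrame:
    """Keep reference rows with speed within ``margin`` of the predicted range.

    ``reference`` must have a ``speed`` column.  Returns rows with
    speed in [min(pred) - margin, max(pred) + margin].
    """
    pred = np.asarray(predicted_speeds, float)
    if pred.size == 0 or len(reference) == 0:
        raise ValueError("empty predicted-speed set or reference")
    lo, hi = pred.min() - margin, pred.max() + margin
    out = reference[(reference["speed"] >= lo) & (reference["speed"] <= hi)]
    if len(out) == 0:
        warnings.warn("no reference points remain after speed cropping", stacklevel=2)
    return out.reset_index(drop=True)


def fm_subset(
    reference: pd.DataFrame, subject_fm: int, window: int = 3
) -> tuple[pd.DataFrame, float, float]:
    """Reference subjects with Fugl-Meyer score within ±window of the subject.

    ``reference`` must have ``fugl_meyer`` and ``cot`` columns.  Returns the
    subset and the mean and SD of its CoT values.
    """
    if len(reference) == 0:
        raise ValueError("empty reference list")
    sub = reference[np.abs(reference["fugl_meyer"] - subject_fm) <= window].reset_index(
        drop=True
    )
    if len(sub) == 0:
        warnings.warn(
            f"no reference subjects within ±{window} of FM {subject_fm}", stacklevel=2
        )
        return sub, float("nan"), float("nan")
    return sub, float(sub["cot"].mean()), float(sub["cot"].std(ddof=1))
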