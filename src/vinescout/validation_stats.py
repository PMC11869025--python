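"""Cross-validation statistics for per-plant bunch counts.

Three counting methods are compared pairwise on the same plants: the
field ground truth (every bunch on the vine, occluded or not), the visual
count an expert makes from the photographs, and the automated pipeline
count. For a pair of methods (x, y) the module reports the OLS trend line
(slope, intercept, R²), the through-origin slope Σxy/Σx² (scatter plots
of counts are naturally anchored at zero, and a sub-unity through-origin
slope reads directly as a systematic undercount fraction), and RMSE.

RMSE here is the root mean square of the *direct* method differences
y − x, i.e. inter-method disagreement in bunches, not the residual of the
fitted line; the fit-residual RMSE is also reported, separately labelled.

Occlusion rate is the count-based fraction of bunches invisible in the
imagery: (GT total − visible total) / GT total.

Group comparisons (diseased vs healthy plants, lighting, capture device)
use Welch's unequal-variance two-sample t-test, two-sided.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass
class RegressionReport:
    """Paired-method comparison: trend line, through-origin slope, RMSE."""

    slope: float
    intercept: float
    r_squared: float
    rmse: float  # sqrt(mean((y - x)^2)): direct inter-method disagreement
    fit_rmse: float  # sqrt(mean(OLS residual^2))
    through_origin_slope: float
    n: int


@dataclasses.dataclass
class GroupComparison:
    t_statistic: float
    p_value: float
    df: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def regress_methods(x, y) -> RegressionReport:
    """Compare paired per-plant counts from two methods."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D samples")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired samples")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; trend line is undefined")
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    sxx = float(np.sum(x * x))
    return RegressionReport(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        rmse=float(np.sqrt(np.mean((y - x) ** 2))),
        fit_rmse=float(np.sqrt(np.mean(resid**2))),
        through_origin_slope=float(np.sum(x * y) / sxx),
        n=n,
    )


def occlusion_rate(gt_total: int, visible_total: int) -> float:
    """Fraction of bunches hidden by foliage: (GT - visible) / GT."""
    if gt_total <= 0:
        raise ValueError("gt_total must be positive")
    if visible_total < 0 or visible_total > gt_total:
        raise ValueError("visible_total must lie in [0, gt_total]")
    return (gt_total - visible_total) / gt_total


def compare_groups(a, b) -> GroupComparison:
    """Welch two-sample t-test (two-sided) between per-plant samples.

    Degenerate case of zero variance in both groups: p = 1 when the means
    are equal (no evidence of difference), p = 0 when they differ.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        same = a.mean() == b.mean()
        return GroupComparison(
            t_statistic=0.0 if same else float("inf"),
            p_value=1.0 if same else 0.0,
            df=float(len(a) + len(b) - 2),
            mean_a=float(a.mean()),
            mean_b=float(b.mean()),
            n_a=len(a),
            n_b=len(b),
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.df),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=len(a),
        n_b=len(b),
    )


def validation_panels(table: pd.DataFrame) -> dict[str, RegressionReport]:
    """Four-panel method comparison from a per-plant table.

    ``table`` needs columns ``gt``, ``visu``, ``model`` and a boolean
    ``esca`` flag. Panels: GT vs Visu and Visu vs Model, each over all
    plants and restricted to disease-free plants.
    """
    required = {"gt", "visu", "model", "esca"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    healthy = table[~table["esca"].astype(bool)]
    return {
        "gt_vs_visu": regress_methods(table["gt"], table["visu"]),
        "visu_vs_model": regress_methods(table["visu"], table["model"]),
        "gt_vs_visu_no_esca": regress_methods(healthy["gt"], healthy["visu"]),
        "visu_vs_model_no_esca": regress_methods(healthy["visu"], healthy["model"]),
    }


def group_tests(table: pd.DataFrame, value: str = "model") -> dict[str, GroupComparison]:
    """Two-group t-tests on per-plant detection differences.

    For each available boolean/binary grouping column (``esca``,
    ``lighting``, ``phone``) the per-plant difference ``value - visu`` is
    compared between the two groups.
    """
    out: dict[str, GroupComparison] = {}
    diff = table[value].astype(float) - table["visu"].astype(float)
    for col in ("esca", "lighting", "phone"):
        if col not in table.columns:
            continue
        flag = table[col]
        levels = sorted(pd.unique(flag))
        if len(levels) != 2:
            continue
        a = diff[flag == levels[0]]
        b = diff[flag == levels[1]]
        if len(a) < 2 or len(b) < 2:
            continue
        out[col] = compare_groups(a, b)
    return out
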