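"""Hierarchical replicate aggregation and significance tests.

The statistical unit is the biological replicate, never the cell: cells
are averaged within each replicate first, and condition-level mean and
SD are computed over the (unweighted) replicate means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "replicate_aggregate",
    "one_way_anova",
    "two_way_anova",
    "paired_t_test",
    "TestResult",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    flag: str = ""


def replicate_aggregate(
    metrics: pd.DataFrame,
    value_cols: Sequence[str],
    condition_col: str = "condition",
    replicate_col: str = "replicate",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-stage aggregation: cell -> replicate mean -> condition mean +/- SD.

    Undefined per-cell values (NaN, e.g. prominence with zero patches)
    are excluded, with exclusion counts reported per replicate.  The
    condition SD is the sample SD over replicate means and is NaN when a
    condition has a single replicate (flagged via ``n_replicates``).
    """
    long = metrics.melt(
        id_vars=[condition_col, replicate_col],
        value_vars=list(value_cols),
        var_name="metric",
    )
    grouped = long.groupby([condition_col, replicate_col, "metric"])["value"]
    rep = grouped.agg(
        mean="mean",
        n_cells="count",
        n_excluded=lambda v: int(v.isna().sum()),
    ).reset_index()

    cond = (
        rep.groupby([condition_col, "metric"])
        .agg(
            mean=("mean", "mean"),
            sd=("mean", lambda v: v.std(ddof=1)),
            n_replicates=("mean", "count"),
            n_cells=("n_cells", "sum"),
        )
        .reset_index()
    )
    return rep, cond


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """Classical one-way fixed-effects ANOVA on replicate means."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return TestResult(0.0, 1.0, flag="all_values_identical")
    f, p = stats.f_oneway(*arrays)
    return TestResult(float(f), float(p))


def two_way_anova(
    df: pd.DataFrame, value_col: str, factor_a: str, factor_b: str
) -> pd.DataFrame:
    """Standard fixed-effects two-way ANOVA (type II) for factorial designs."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    data = df.rename(
        columns={value_col: "y", factor_a: "fa", factor_b: "fb"}
    )[["y", "fa", "fb"]]
    model = ols("y ~ C(fa) * C(fb)", data=data).fit()
    return sm.stats.anova_lm(model, typ=2)


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-tailed paired t test on per-replicate pairs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need paired samples of equal length >= 2")
    diff = a - b
    if np.ptp(diff) == 0:
        if diff[0] == 0:
            return TestResult(0.0, 1.0, flag="zero_variance")
        return TestResult(np.nan, np.nan, flag="zero_variance")
    t, p = stats.ttest_rel(a, b)
    return TestResult(float(t), float(p))
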