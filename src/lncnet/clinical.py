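"""Clinical summary statistics: group means +/- SD, two-sample t-tests and
Pearson correlation with exact two-sided p-values.

Summaries use the sample standard deviation (n-1 denominator); the t-test
accepts either raw values or (n, mean, sd) summaries, because published
cohort tables often print only group summaries for one arm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ClinicalSummary:
    variable: str
    n: int
    mean: float
    sd: float

    def formatted(self, decimals: int = 2) -> str:
        return f"{self.mean:.{decimals}f} ± {self.sd:.{decimals}f}"


@dataclass(frozen=True)
class GroupSummary:
    """(n, mean, sd) stand-in for raw values of one group."""

    n: int
    mean: float
    sd: float


def summarize(values: Sequence[float], variable: str = "") -> ClinicalSummary:
    """Mean and sample SD (n-1). Rounding happens only at presentation."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2 or not np.isfinite(arr).all():
        raise ValueError("need >= 2 finite values")
    return ClinicalSummary(variable, int(arr.size), float(arr.mean()), float(arr.std(ddof=1)))


def _as_summary(g) -> GroupSummary:
    if isinstance(g, GroupSummary):
        return g
    if isinstance(g, ClinicalSummary):
        return GroupSummary(g.n, g.mean, g.sd)
    arr = np.asarray(g, dtype=float)
    if arr.size < 2:
        raise ValueError("each group needs n >= 2")
    return GroupSummary(int(arr.size), float(arr.mean()), float(arr.std(ddof=1)))


def two_sample_t(group_a, group_b, variant: str = "student") -> tuple[float, float, float]:
    """Two-sided two-sample t-test; returns (t, df, p).

    ``variant='student'`` pools the variance (df = n1+n2-2);
    ``variant='welch'`` uses the Satterthwaite df. Zero variance in both
    groups: p = 1 when the means are equal (no evidence), p = 0 with
    t = +/-inf when they differ (the degenerate certain case).
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    a, b = _as_summary(group_a), _as_summary(group_b)
    if a.sd == 0.0 and b.sd == 0.0:
        if a.mean == b.mean:
            return 0.0, float(a.n + b.n - 2), 1.0
        t = np.inf if a.mean > b.mean else -np.inf
        return float(t), float(a.n + b.n - 2), 0.0
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=(variant == "student")
    )
    if variant == "student":
        df = a.n + b.n - 2
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with the exact two-sided p from t = r sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def summarize_table(
    clinical: pd.DataFrame,
    control_summaries: dict[str, GroupSummary] | None = None,
    variant: str = "student",
) -> pd.DataFrame:
    """Cohort feature table: per-variable mean +/- SD and, where a control
    summary is supplied, the two-sample t-test p-value against it."""
    control_summaries = control_summaries or {}
    rows = []
    for col in clinical.columns:
        if col == "patient":
            continue
        s = summarize(clinical[col].to_numpy(), variable=col)
        ctrl = control_summaries.get(col)
        p = np.nan
        ctrl_str = "-"
        if ctrl is not None:
            _, _, p = two_sample_t(ctrl, clinical[col].to_numpy(), variant=variant)
            ctrl_str = f"{ctrl.mean:.2f} ± {ctrl.sd:.2f}"
        rows.append(
            {
                "variable": col,
                "n": s.n,
                "control": ctrl_str,
                "case": s.formatted(),
                "mean": round(s.mean, 2),
                "sd": round(s.sd, 2),
                "p_value": round(p, 3) if np.isfinite(p) else np.nan,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "ClinicalSummary",
    "GroupSummary",
    "pearson_with_p",
    "summarize",
    "summarize_table",
    "two_sample_t",
]
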