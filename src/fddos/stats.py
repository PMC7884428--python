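"""Nonparametric association statistics and median [IQR] summary tables.

The cohort analyses are deliberately nonparametric: subject-level epoch
summaries are skewed, so groups are described by median and interquartile
range and compared with Wilcoxon tests (signed-rank within subject between
epochs, rank-sum between outcome groups) at alpha = 0.05, and the CPR
strategy x outcome contingency is tested with Fisher's exact test.  No
multiple-testing correction is applied, matching the reporting convention of
the source analyses.

Conventions pinned here (unstated in the field reports this mirrors):
quantiles use linear interpolation between order statistics; zero
differences in the signed-rank test are dropped (Wilcoxon's original
treatment); exact null distributions are used for small samples without
ties, tie/continuity-corrected normal approximations otherwise, and the
method actually used is recorded on every result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "signed_rank_test",
    "rank_sum_test",
    "fisher_exact",
    "median_iqr",
    "format_median_iqr",
    "group_comparison_table",
]

#: largest sample size for which the exact signed-rank null is enumerated
EXACT_N_MAX = 25


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: int
    warning: str | None = None


def signed_rank_test(differences) -> TestResult:
    """Wilcoxon signed-rank test of paired differences against zero.

    Zero differences are dropped before ranking.  The exact null distribution
    is used for n <= 25 when the absolute differences are tie-free; otherwise
    a tie/continuity-corrected normal approximation.  All-zero input returns
    p = 1 with a warning rather than an error.
    """
    d = np.asarray(differences, dtype=float)
    d = d[np.isfinite(d)]
    nz = d[d != 0.0]
    if nz.size == 0:
        return TestResult(0.0, 1.0, "degenerate (all zero differences)", 0,
                          warning="all differences are zero")
    has_ties = np.unique(np.abs(nz)).size < nz.size
    if nz.size <= EXACT_N_MAX and not has_ties:
        method = "exact"
        res = sps.wilcoxon(nz, zero_method="wilcox", mode="exact")
    else:
        method = "normal approximation, tie/continuity corrected"
        res = sps.wilcoxon(nz, zero_method="wilcox", mode="approx", correction=True)
    return TestResult(float(res.statistic), float(res.pvalue), method, int(nz.size))


def rank_sum_test(a, b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test between two groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and max(a.size, b.size) <= EXACT_N_MAX:
        method = "exact"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "normal approximation, tie corrected"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)), method,
                      int(a.size + b.size))


def fisher_exact(table, sided: str = "two-sided") -> TestResult:
    """Fisher exact test on a 2x2 contingency table.

    ``sided`` is ``"two-sided"``, ``"greater"`` or ``"less"``; one-sided
    alternatives refer to the (0,0) cell relative to its hypergeometric
    expectation.  A zero margin gives p = 1 with a warning.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("table must be 2x2 non-negative integer counts")
        t = t.astype(int)
    n = int(t.sum())
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return TestResult(np.nan, 1.0, "degenerate (zero margin)", n,
                          warning="a table margin is zero")
    alternative = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[sided]
    odds, p = sps.fisher_exact(t, alternative=alternative)
    return TestResult(float(odds), float(p), f"hypergeometric exact ({sided})", n)


def median_iqr(values) -> tuple[float, float, float]:
    """(median, q1, q3) using linear interpolation between order statistics."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("empty input")
    q1, med, q3 = np.percentile(v, [25.0, 50.0, 75.0])
    return float(med), float(q1), float(q3)


def format_median_iqr(values, fmt: str = "{:.1f}") -> str:
    med, q1, q3 = median_iqr(values)
    return f"{fmt.format(med)} [{fmt.format(q1)}, {fmt.format(q3)}]"


def group_comparison_table(
    df: pd.DataFrame,
    value_cols,
    group_col: str = "rosc",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Median [IQR] per group and rank-sum p for each parameter column.

    ``group_col`` must be boolean (True = ROSC).  Missing values are dropped
    per parameter; a parameter with an empty group yields NaN p.
    """
    g = df[group_col].astype(bool)
    rows = []
    for col in value_cols:
        v = df[col].astype(float)
        a = v[g & v.notna()].to_numpy()
        b = v[~g & v.notna()].to_numpy()
        row = {"parameter": col}
        row["rosc_median_iqr"] = format_median_iqr(a) if a.size else ""
        row["no_rosc_median_iqr"] = format_median_iqr(b) if b.size else ""
        if a.size and b.size:
            res = rank_sum_test(a, b)
            row["p_value"] = res.p_value
            row["test"] = f"Wilcoxon rank-sum ({res.method})"
            row["significant"] = res.p_value < alpha
        else:
            row["p_value"] = np.nan
            row["test"] = ""
            row["significant"] = False
        rows.append(row)
    return pd.DataFrame(rows)
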