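"""Classical tests for covariate balance and verification analyses.

Covers the group comparisons the study design needs: Welch's t for
continuous covariates, Fisher's exact test for binary ones, the
Wilcoxon rank-sum test (exact for small samples) and Pearson
correlation for qPCR verification, plus the delta-Ct transform itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


class InsufficientDataError(ValueError):
    """A group is too small or degenerate for the requested test."""


@dataclass
class TestResult:
    statistic: float
    p: float
    method: str
    df: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside [0, 1]")


@dataclass
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows are groups, columns yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 or x != int(x) for x in cells):
            raise ValueError("cell counts must be non-negative integers")
        if sum(cells) == 0:
            raise ValueError("table total is zero")


def welch_t(group1, group2) -> TestResult:
    """Welch's unequal-variance two-sample t-test, two-sided."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        raise InsufficientDataError("each group needs at least 2 values")
    if g1.var(ddof=1) == 0 and g2.var(ddof=1) == 0:
        if g1.mean() == g2.mean():
            return TestResult(0.0, 1.0, "welch_t", df=float(len(g1) + len(g2) - 2))
        raise InsufficientDataError("both groups constant with different means")
    res = sps.ttest_ind(g1, g2, equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue), "welch_t", df=float(res.df))


def fisher_exact(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    With margins fixed, the two-sided p sums the hypergeometric
    probability of every table whose point probability does not exceed
    the observed one (with a 1e-7 relative slack against float ties) —
    the convention of the usual R implementation.  The reported
    statistic is the sample odds ratio.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    row1 = a + b
    n1 = a + c  # first-column margin
    N = a + b + c + d
    lo = max(0, row1 - (N - n1))
    hi = min(row1, n1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, N, n1, row1)
    p_obs = sps.hypergeom.pmf(a, N, n1, row1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    if b * c > 0:
        odds = (a * d) / (b * c)
    else:
        odds = math.inf if a * d > 0 else math.nan
    return TestResult(odds, min(p, 1.0), "fisher_exact")


def _rank_sum_exact_p(values: np.ndarray, n1: int, observed: float) -> float:
    """Two-sided p for the rank-sum by full enumeration of group splits."""
    ranks = sps.rankdata(values)  # mid-ranks for ties
    total = 0
    le = 0
    ge = 0
    eps = 1e-9
    for idx in combinations(range(len(values)), n1):
        rs = ranks[list(idx)].sum()
        total += 1
        if rs <= observed + eps:
            le += 1
        if rs >= observed - eps:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def wilcoxon_rank_sum(
    group1, group2, exact_below_n: int = 25, max_enumeration: int = 500_000
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    For small samples (both groups below ``exact_below_n`` and at most
    ``max_enumeration`` group splits) the exact permutation null of the
    rank-sum is enumerated, with mid-ranks for ties; otherwise the
    normal approximation with tie correction and continuity correction
    is used.  The statistic is group 1's rank sum.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if len(g1) == 0 or len(g2) == 0:
        raise InsufficientDataError("both groups must be non-empty")
    n1, n2 = len(g1), len(g2)
    values = np.concatenate([g1, g2])
    ranks = sps.rankdata(values)
    rs = float(ranks[:n1].sum())
    if (
        n1 < exact_below_n
        and n2 < exact_below_n
        and math.comb(n1 + n2, n1) <= max_enumeration
    ):
        p = _rank_sum_exact_p(values, n1, rs)
        return TestResult(rs, p, "wilcoxon_exact")
    res = sps.mannwhitneyu(g1, g2, alternative="two-sided", method="asymptotic")
    return TestResult(rs, float(res.pvalue), "wilcoxon_normal")


def pearson_correlation(x, y) -> TestResult:
    """Pearson's r with the two-sided t-based p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InsufficientDataError("need n >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InsufficientDataError("correlation undefined for a constant vector")
    res = sps.pearsonr(x, y)
    return TestResult(float(res.statistic), float(res.pvalue), "pearson", df=float(len(x) - 2))


def qpcr_delta_ct(target_ct, reference_ct) -> np.ndarray:
    """Per-sample delta-Ct: target Ct minus reference (control-gene) Ct.

    Each element of either input may be a scalar or a sequence of
    technical replicates (e.g. duplicates), which are averaged first.
    """

    def _collapse(values) -> np.ndarray:
        return np.array(
            [float(np.mean(v)) if np.ndim(v) else float(v) for v in values]
        )

    t = _collapse(target_ct)
    r = _collapse(reference_ct)
    if len(t) != len(r):
        raise ValueError(f"unpaired inputs: {len(t)} target vs {len(r)} reference")
    return t - r


def covariate_balance_table(
    cohort: pd.DataFrame, assignments: pd.DataFrame
) -> pd.DataFrame:
    """Group-balance report between SY and non-SY subjects.

    For each covariate, summarizes both groups and tests the marginal
    difference — Welch's t for continuous covariates (age, BMI, UV
    score), Fisher's exact test for binary ones (smoking, prior skin
    cancer).  Refuses to compare when a group is empty.
    """
    merged = cohort.join(assignments["class"])
    sy = merged[merged["class"] == "SY"]
    nonsy = merged[merged["class"] == "non-SY"]
    if len(sy) == 0 or len(nonsy) == 0:
        raise InsufficientDataError("SY or non-SY group is empty")

    rows = []
    for col, label in [("age", "Chronological age, years"),
                       ("bmi", "Body mass index, kg/m2"),
                       ("uv_score", "Lifetime UV score")]:
        if col not in merged:
            continue
        res = welch_t(sy[col], nonsy[col])
        rows.append(
            {
                "parameter": label,
                "sy_summary": f"{sy[col].mean():.1f} ({sy[col].std(ddof=1):.1f})",
                "nonsy_summary": f"{nonsy[col].mean():.1f} ({nonsy[col].std(ddof=1):.1f})",
                "test": res.method,
                "p": res.p,
            }
        )
    for col, label in [("smoking", "Smoking history: yes"),
                       ("skin_cancer", "Previous skin cancer: yes")]:
        if col not in merged:
            continue
        a, b = int(sy[col].sum()), int((~sy[col].astype(bool)).sum())
        c, d = int(nonsy[col].sum()), int((~nonsy[col].astype(bool)).sum())
        res = fisher_exact(ContingencyTable2x2(a, b, c, d))
        rows.append(
            {
                "parameter": label,
                "sy_summary": f"{a} ({100 * a / len(sy):.0f}%)",
                "nonsy_summary": f"{c} ({100 * c / len(nonsy):.0f}%)",
                "test": res.method,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)
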