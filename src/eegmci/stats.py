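"""Univariate statistics used throughout the cohort comparisons.

Group contrasts are nonparametric (the cohort variables are mostly
non-normal, which the Shapiro-Wilk check documents): Wilcoxon rank-sum
with Bonferroni correction for continuous variables, Yates-corrected
Pearson chi-squared for 2x2 categorical tables, Spearman rank correlation
for associations.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    p: float
    method: str
    n: tuple[int, ...]
    corrected_p: float | None = None
    family_size: int | None = None
    note: str | None = None


def wilcoxon_ranksum(x, y, exact_below: int = 10) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    The null is enumerated exactly when both samples have at most
    ``exact_below`` observations and there are no ties; otherwise the
    normal approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("all pooled values identical; p = 1", stacklevel=2)
        return TestResult(statistic=0.0, p=1.0, method="wilcoxon-ranksum",
                          n=(len(x), len(y)), note="degenerate")
    ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= exact_below and len(y) <= exact_below and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue),
                      method=f"wilcoxon-ranksum ({method})",
                      n=(len(x), len(y)))


def chisq_2x2(table, continuity: bool = True) -> TestResult:
    """Pearson chi-squared test on a 2x2 count table, df = 1.

    Yates continuity correction (|O - E| reduced by 0.5, floored at 0) is
    applied by default.
    """
    t = np.asarray(table, float)
    if t.shape != (2, 2) or np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table must be 2x2 nonnegative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal total; test undefined")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    dev = np.abs(t - expected)
    if continuity:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev**2 / expected).sum())
    p = float(sps.chi2.sf(stat, df=1))
    return TestResult(statistic=stat, p=p,
                      method="pearson-chisq" + ("-yates" if continuity else ""),
                      n=tuple(int(v) for v in t.sum(axis=1)))


def spearman(x, y) -> TestResult:
    """Spearman rank correlation (average ranks for ties, t-approximation p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance in ranks; correlation undefined",
                      stacklevel=2)
        return TestResult(statistic=np.nan, p=np.nan, method="spearman",
                          n=(len(x),), note="degenerate")
    rs, p = sps.spearmanr(x, y)
    return TestResult(statistic=float(rs), p=float(p), method="spearman",
                      n=(len(x),))


def shapiro_wilk(x) -> TestResult:
    """Shapiro-Wilk normality test (annotation only; downstream tests stay
    nonparametric regardless of the outcome)."""
    x = np.asarray(x, float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    res = sps.shapiro(x)
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue),
                      method="shapiro-wilk", n=(len(x),))


def bonferroni(pvals, family_size: int | None = None) -> list[float]:
    """Bonferroni correction: each p multiplied by the family size, capped at 1."""
    pvals = list(pvals)
    m = family_size if family_size is not None else len(pvals)
    if m < len(pvals):
        raise ValueError("family_size must be >= number of p-values")
    return [min(1.0, p * m) for p in pvals]


def with_bonferroni(results: list[TestResult],
                    family_size: int | None = None) -> list[TestResult]:
    """Attach corrected p-values to a family of test results."""
    m = family_size if family_size is not None else len(results)
    corrected = bonferroni([r.p for r in results], m)
    for r, cp in zip(results, corrected):
        r.corrected_p = cp
        r.family_size = m
    return results
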