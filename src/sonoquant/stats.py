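"""Nonparametric group statistics: Wilcoxon signed-rank, Kruskal-Wallis,
Benjamini-Hochberg.

These are implemented self-contained so the exact small-sample behaviour
is fully specified:

* The Wilcoxon signed-rank test drops zero differences (the classic
  convention), mid-ranks ties, and reports ``W`` = the sum of positive
  signed ranks.  For n <= 25 the two-sided p-value is computed *exactly*
  by enumerating the null distribution of W over all 2^n sign
  assignments (a shift/convolution recurrence over doubled ranks, so
  mid-ranks are handled exactly); above that a normal approximation with
  continuity and tie corrections is used.  A study-sized cohort (n = 9)
  therefore always gets an exact p.
* Kruskal-Wallis H uses the standard rank formula with tie correction
  and a chi-square reference distribution on (groups - 1) degrees of
  freedom.
* Benjamini-Hochberg returns step-up adjusted p-values
  ``q_(i) = min_{j >= i} (m * p_(j) / j)`` clipped at 1.

All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ParameterError, SampleSizeError

#: Sample size at which Wilcoxon switches from exact enumeration to the
#: normal approximation.
EXACT_LIMIT = 25


@dataclass
class TestResult:
    statistic_name: str  # W | H
    statistic: float
    p_value: float
    n: int
    method: str  # exact | normal-approx | chi-square | degenerate

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ParameterError(f"p-value {self.p_value} outside [0, 1]")


def _signed_rank_distribution(double_ranks: np.ndarray) -> np.ndarray:
    """Counts of each doubled-W value over all sign assignments.

    ``double_ranks`` are the tie-corrected ranks times two (integers even
    with mid-ranks); entry ``counts[w]`` is the number of the 2^n sign
    vectors whose positive-rank sum equals ``w / 2``.
    """
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in double_ranks:
        r = int(r)
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    return counts


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; if every difference is zero the result
    is degenerate (W = 0, p = 1, method "degenerate").
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("paired samples must be 1-D and of equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult("W", 0.0, 1.0, 0, "degenerate")
    if n < 3:
        raise SampleSizeError(f"need >= 3 nonzero differences, got {n}")
    ranks = sps.rankdata(np.abs(d))  # mid-ranks for ties
    w = float(ranks[d > 0].sum())
    if n <= EXACT_LIMIT:
        double_ranks = np.rint(2 * ranks).astype(int)
        counts = _signed_rank_distribution(double_ranks)
        total = counts.sum()  # 2^n
        dw = int(round(2 * w))
        p_le = counts[: dw + 1].sum() / total
        p_ge = counts[dw:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult("W", w, p, n, "exact")
    # normal approximation with tie and continuity corrections
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return TestResult("W", w, 1.0, n, "degenerate")
    z = (w - mean - 0.5 * np.sign(w - mean)) / np.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult("W", w, p, n, "normal-approx")


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ParameterError("p-values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def kruskal_wallis(groups: list[np.ndarray]) -> TestResult:
    """Kruskal-Wallis H-test across two or more independent groups.

    H is tie-corrected; the p-value comes from the chi-square
    distribution with (number of groups - 1) degrees of freedom.  If all
    values are identical the result is degenerate (H = 0, p = 1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ParameterError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ParameterError("groups must be non-empty")
    pooled = np.concatenate(groups)
    n = pooled.size
    if n < 3:
        raise SampleSizeError("need at least 3 observations in total")
    if np.all(pooled == pooled[0]):
        return TestResult("H", 0.0, 1.0, n, "degenerate")
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += g.size * (r.mean() - (n + 1) / 2.0) ** 2
        start += g.size
    h *= 12.0 / (n * (n + 1))
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(np.sum(tie_counts**3 - tie_counts)) / (n**3 - n)
    if correction <= 0:
        return TestResult("H", 0.0, 1.0, n, "degenerate")
    h /= correction
    p = float(sps.chi2.sf(h, len(groups) - 1))
    return TestResult("H", float(h), p, n, "chi-square")
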