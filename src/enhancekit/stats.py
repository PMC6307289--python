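"""The three statistical procedures used throughout the analysis.

* 2x2 Pearson chi-square (uncorrected; Yates behind a flag) for comparing
  proportions between peak sets,
* unpaired Wilcoxon rank-sum test for comparing signal distributions,
* Pearson correlation test for the H3K27ac / expression relationship.

All tests are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "chi2_2x2_pearson",
    "wilcoxon_rank_sum",
    "pearson_test",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = peak sets, columns = in/out of category."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be > 0")

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def chi2_2x2_pearson(t: ContingencyTable2x2, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square statistic n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) and
    its upper-tail p-value on 1 df. ``yates`` applies the continuity
    correction (|ad-bc| reduced by n/2 before squaring)."""
    r1, r2, c1, c2 = t.margins
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-square test undefined with a zero margin")
    n = r1 + r2
    diff = abs(t.a * t.d - t.b * t.c)
    if yates:
        diff = max(0.0, diff - n / 2.0)
    chi2 = n * diff**2 / (r1 * r2 * c1 * c2)
    p = float(sps.chi2.sf(chi2, df=1))
    return float(chi2), p


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided unpaired Wilcoxon rank-sum test.

    Returns (W, p) where W is the rank-sum of the first sample using
    midranks for ties. The p-value is exact (full enumeration of rank
    assignments) when n_a + n_b <= 20 and there are no ties, otherwise a
    normal approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    W = float(ranks[: a.size].sum())
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical in both samples", stacklevel=2)
        return W, 1.0
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (a.size + b.size <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return W, float(min(1.0, res.pvalue))


def pearson_test(x, y) -> tuple[float, float]:
    """Pearson correlation r with the two-sided p-value from
    t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
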