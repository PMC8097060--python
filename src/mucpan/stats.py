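"""Shared statistical kernel.

Every comparison in the pipeline funnels through the handful of tests here:
2x2 association (Fisher exact or Pearson chi-square), the Mann-Whitney U rank
test, Spearman rank correlation, Benjamini-Hochberg FDR adjustment, and the
Monte-Carlo empirical p-value formula p = (r+1)/(n+1).

Conventions
-----------
* Fisher's exact test is two-sided by summation of tables whose point
  probability does not exceed the observed table's (scipy's convention).
* Pearson chi-square is computed without Yates continuity correction.
* ``method="auto"`` picks Fisher whenever any expected cell count is below 5,
  Pearson chi-square otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Table2x2",
    "Assoc2x2Result",
    "empirical_p",
    "assoc_test_2x2",
    "mann_whitney",
    "spearman",
    "bh_fdr",
]

#: Exact Mann-Whitney p-values are used up to this per-group size (tie-free
#: samples only); beyond it the normal approximation with tie correction.
MANN_WHITNEY_EXACT_MAX_N = 25


@dataclass(frozen=True)
class Table2x2:
    """A 2x2 contingency table; rows index group, columns feature status.

    Layout::

              feature+  feature-
        grp1     a         b
        grp2     c         d
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        for name, v in zip("abcd", cells):
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name!r} must be a non-negative integer, got {v!r}")
        if sum(cells) == 0:
            raise ValueError("table has no observations (all cells zero)")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @property
    def degenerate(self) -> bool:
        """True when an entire row or column is zero (no association testable)."""
        m = self.as_array()
        return bool((m.sum(axis=0) == 0).any() or (m.sum(axis=1) == 0).any())


@dataclass(frozen=True)
class Assoc2x2Result:
    odds_ratio: float  # a*d / (b*c); inf on zero b*c, nan when undefined
    p_value: float
    method: str  # "fisher" or "chisq" actually applied
    statistic: float  # chi-square statistic (nan for fisher)
    degenerate: bool


def empirical_p(r: int, n: int) -> float:
    """Monte-Carlo empirical p-value ``(r + 1) / (n + 1)``.

    ``r`` is the number of simulations meeting or exceeding the observed
    statistic, out of ``n`` total.  The +1 offsets guarantee the result lies
    in ``(0, 1]`` — an empirical p of exactly zero is never reported.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= r <= n:
        raise ValueError(f"r must satisfy 0 <= r <= n, got r={r}, n={n}")
    return float(Fraction(r + 1, n + 1))


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    num, den = a * d, b * c
    if den == 0:
        return float("inf") if num > 0 else float("nan")
    return num / den


def assoc_test_2x2(table: Table2x2, method: str = "auto") -> Assoc2x2Result:
    """Association test on a 2x2 table.

    Parameters
    ----------
    table
        Cell counts.
    method
        ``"fisher"``: two-sided exact conditional test (point-probability
        summation).  ``"chisq"``: Pearson chi-square without continuity
        correction.  ``"auto"``: Fisher when any expected cell count < 5,
        chi-square otherwise.

    Degenerate tables (a whole row or column zero) return p = 1 with an
    undefined odds ratio and ``degenerate=True``.
    """
    if method not in ("fisher", "chisq", "auto"):
        raise ValueError(f"unknown method {method!r}")
    m = table.as_array()
    orat = _odds_ratio(table.a, table.b, table.c, table.d)

    if table.degenerate:
        return Assoc2x2Result(float("nan"), 1.0, method, float("nan"), True)

    if method == "auto":
        expected = sps.contingency.expected_freq(m)
        method = "fisher" if (expected < 5).any() else "chisq"

    if method == "fisher":
        res = sps.fisher_exact(m, alternative="two-sided")
        return Assoc2x2Result(orat, float(res.pvalue), "fisher", float("nan"), False)
    chi2 = sps.chi2_contingency(m, correction=False)
    return Assoc2x2Result(orat, float(chi2.pvalue), "chisq", float(chi2.statistic), False)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns ``(U, p)``.

    Exact null distribution when both groups have at most
    ``MANN_WHITNEY_EXACT_MAX_N`` observations and no value is shared between
    or within groups; otherwise the normal approximation with tie correction
    and continuity correction.  If every value in both samples is identical
    the test is vacuous and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    small = max(x.size, y.size) <= MANN_WHITNEY_EXACT_MAX_N
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns ``(rho, p)``; p is the t-distribution approximation.  A constant
    input vector makes the correlation undefined: ``(nan, nan)`` is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired (equal length)")
    if x.size < 3:
        raise ValueError(f"need at least 3 paired observations, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved.

    q >= p elementwise and q is monotone non-decreasing when sorted by p.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
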