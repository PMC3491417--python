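"""Statistical kernel: proportion-equality tests, Mann-Whitney U, Spearman.

The proportion tests follow the classic chi-square-with-continuity-correction
formulation (the style of R's ``prop.test`` defaults): the absolute deviation
from expectation is reduced by 0.5 before squaring, with the correction
magnitude capped so the corrected deviation never goes negative. Two-sided
p-values throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "DegenerateTableError",
    "TestResult",
    "two_proportion_test",
    "one_proportion_test",
    "mann_whitney",
    "spearman",
    "significance_stars",
    "benjamini_hochberg",
]


class DegenerateTableError(ValueError):
    """The contingency table has a zero margin; the test is undefined."""


def significance_stars(p: float) -> str:
    """Star annotation: *** p<0.001, ** p<0.01, * p<0.05 (strict)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value out of [0,1]: {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)

    def to_row(self) -> Tuple[float, float, str, str]:
        return (self.statistic, self.p_value, self.stars, self.method)


def _check_count(x: int, n: int) -> None:
    if n < 1:
        raise DegenerateTableError(f"sample size must be >= 1, got {n}")
    if not 0 <= x <= n:
        raise ValueError(f"count {x} out of [0, {n}]")


def two_proportion_test(x1: int, n1: int, x2: int, n2: int,
                        continuity: bool = True) -> TestResult:
    """Two-sample test of equal proportions.

    With ``continuity``, a Yates-corrected chi-square on the 2x2 table
    (two-sided p from chi-square with 1 df). Without, the pooled-variance
    two-sample z-test; the statistic is then the signed z.
    """
    _check_count(x1, n1)
    _check_count(x2, n2)
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise DegenerateTableError(
            f"degenerate 2x2 table: pooled proportion {pooled} leaves a zero margin")
    if continuity:
        dev = abs(x1 - n1 * pooled)  # equal for all four cells of a 2x2 table
        corrected = max(dev - min(0.5, dev), 0.0)
        expected = (n1 * pooled, n1 * (1 - pooled), n2 * pooled, n2 * (1 - pooled))
        stat = sum(corrected ** 2 / e for e in expected)
        p = float(sps.chi2.sf(stat, df=1))
        return TestResult(stat, p, "two-proportion chi-square (Yates)")
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = float(2 * sps.norm.sf(abs(z)))
    return TestResult(z, p, "two-proportion z-test (pooled)")


def one_proportion_test(x: int, n: int, p0: float,
                        continuity: bool = True) -> TestResult:
    """One-sample chi-square test of H0: p = p0 (Yates-corrected on request)."""
    _check_count(x, n)
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must be in (0,1), got {p0}")
    dev = abs(x - n * p0)
    if continuity:
        dev = max(dev - min(0.5, dev), 0.0)
    stat = dev ** 2 / (n * p0 * (1 - p0))
    p = float(sps.chi2.sf(stat, df=1))
    method = "one-proportion chi-square" + (" (Yates)" if continuity else "")
    return TestResult(stat, p, method)


EXACT_MWU_MAX = 12  # largest min(n, m) for which the exact method is auto-selected


@lru_cache(maxsize=None)
def _u_count_distribution(n: int, m: int) -> Tuple[int, ...]:
    """Number of rank arrangements giving each U value for sample sizes n, m.

    Classic recurrence c(n, m, u) = c(n-1, m, u-m) + c(n, m-1, u) over the
    count of arrangements; index u runs 0 .. n*m.
    """
    counts = np.zeros((n + 1, m + 1, n * m + 1), dtype=np.int64)
    counts[0, :, 0] = 1
    counts[:, 0, 0] = 1
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            c = counts[i, j - 1].copy()
            c[j:] += counts[i - 1, j, : c.size - j]
            counts[i, j] = c
    return tuple(int(v) for v in counts[n, m, : n * m + 1])


def _exact_mwu_p(u: float, n: int, m: int) -> float:
    """Two-sided exact p: 2 * min tail of the null U distribution, capped at 1."""
    dist = _u_count_distribution(n, m)
    total = math.comb(n + m, n)
    k = int(u)
    lower = sum(dist[: k + 1])
    upper = sum(dist[k:])
    return min(1.0, 2 * min(lower, upper) / total)


def mann_whitney(a: Sequence[float], b: Sequence[float],
                 method: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test.

    method='exact' enumerates the null distribution of U (no ties only;
    falls back to the normal approximation with a method-note when ties are
    present). method='normal_approx' uses the tie-corrected normal
    approximation. method='auto' picks exact when min(n,m) <= 12 and there
    are no ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if method not in ("auto", "exact", "normal_approx"):
        raise ValueError(f"unknown method {method!r}")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    n, m = a.size, b.size
    ranks = sps.rankdata(pooled)  # midranks
    u1 = float(np.sum(ranks[:n]) - n * (n + 1) / 2)

    use_exact = (method == "exact" or
                 (method == "auto" and min(n, m) <= EXACT_MWU_MAX)) and not has_ties
    if use_exact:
        p = _exact_mwu_p(min(u1, n * m - u1), n, m)
        return TestResult(u1, p, "Mann-Whitney U (exact)")

    # normal approximation with tie-corrected variance
    note = " [ties: exact unavailable]" if method == "exact" and has_ties else ""
    mu = n * m / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / ((n + m) * (n + m - 1))
    var = n * m / 12 * (n + m + 1 - tie_term)
    if var == 0:
        return TestResult(u1, 1.0, "Mann-Whitney U (normal approx, zero variance)" + note)
    z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / math.sqrt(var)  # continuity-corrected
    p = float(min(1.0, 2 * sps.norm.sf(abs(z))))
    return TestResult(u1, p, "Mann-Whitney U (normal approx)" + note)


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with midrank ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("correlation undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return TestResult(float(rho), float(p), "Spearman rank correlation")


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional multiple-testing control)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * p.size / (np.arange(p.size) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adjusted, 1.0)
    return out
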