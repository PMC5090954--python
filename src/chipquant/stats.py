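"""Exact-where-it-matters implementations of the two tests the pipeline uses.

Both are written against brute-force-verifiable contracts: the Wilcoxon
signed-rank null distribution is built by convolution over (doubled, hence
integer) mid-ranks, which is algebraically identical to enumerating all 2^n
sign assignments; the Spearman p-value comes from the asymptotic t
approximation on mid-ranks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import stdtr
from scipy.stats import rankdata

from .model import ChipquantError

__all__ = ["TestResult", "wilcoxon_signed_rank", "spearman"]

#: pairs up to which the exact signed-rank distribution is used
EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_effective: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ChipquantError(f"p-value {self.p_value} outside [0, 1]")


@lru_cache(maxsize=256)
def _signed_rank_distribution(doubled_ranks: tuple[int, ...]) -> np.ndarray:
    """Null distribution of the doubled positive-rank sum.

    Returns counts[t] = number of the 2^n sign assignments with doubled
    rank sum t; built by iterated convolution, equivalent to full
    enumeration but O(n * total) instead of O(2^n).
    """
    total = sum(doubled_ranks)
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    upper = 0
    for r in doubled_ranks:
        counts[r : upper + r + 1] += counts[: upper + 1]
        upper += r
    return counts


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped (classic Wilcoxon convention); ties among
    |differences| get mid-ranks.  For n_effective <= 25 the p-value is exact
    (full sign-assignment distribution); above that a normal approximation
    with tie and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ChipquantError("wilcoxon_signed_rank requires equal-length 1-d vectors")
    if len(x) < 2:
        raise ChipquantError("wilcoxon_signed_rank requires at least 2 pairs")
    d = x - y
    d = d[d != 0.0]
    n = len(d)
    if n < 2:
        raise ChipquantError(
            f"fewer than 2 nonzero paired differences (n_effective={n})"
        )
    ranks = rankdata(np.abs(d))  # mid-ranks; may be half-integers
    t_plus = float(ranks[d > 0].sum())

    if n <= EXACT_WILCOXON_MAX_N:
        doubled = tuple(int(round(2 * r)) for r in sorted(ranks))
        counts = _signed_rank_distribution(doubled)
        total = counts.sum()
        t2 = int(round(2 * t_plus))
        cdf = counts[: t2 + 1].sum() / total
        sf = counts[t2:].sum() / total
        p = min(1.0, 2.0 * min(cdf, sf))
        method = "wilcoxon-signed-rank-exact"
    else:
        mu = n * (n + 1) / 4.0
        tie_counts = np.unique(ranks, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (
            (tie_counts**3 - tie_counts).sum() / 48.0
        )
        diff = t_plus - mu
        cc = 0.5 * np.sign(diff)
        z = (diff - cc) / math.sqrt(var)
        p = min(1.0, math.erfc(abs(z) / math.sqrt(2.0)))
        method = "wilcoxon-signed-rank-normal-approx"
    return TestResult(statistic=t_plus, p_value=p, method=method, n_effective=n)


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with the asymptotic t approximation.

    rho is the Pearson correlation of mid-ranks; the two-sided p-value comes
    from t = rho * sqrt((n - 2) / (1 - rho^2)) with n - 2 degrees of
    freedom.  |rho| = 1 is reported with p = 0 and a flag in the method
    string, since the t statistic diverges there.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ChipquantError("spearman requires equal-length 1-d vectors")
    n = len(x)
    if n < 4:
        raise ChipquantError("spearman requires at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ChipquantError("spearman undefined for constant input")
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) >= 1.0 - 1e-14:
        return TestResult(
            statistic=rho,
            p_value=0.0,
            method="spearman-t-approx|rho-degenerate",
            n_effective=n,
        )
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * float(stdtr(n - 2, -abs(t)))
    return TestResult(
        statistic=rho, p_value=min(1.0, p), method="spearman-t-approx", n_effective=n
    )
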