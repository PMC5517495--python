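"""Exact binomial selection-pressure tests and the concordance suite.

The binomial lower tail is evaluated in log space from first principles
(the tail primitive is deliberately not delegated to a library CDF so the
test suite can cross-check it against both brute-force enumeration and an
independent implementation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import fisher_exact, kendalltau, pearsonr, spearmanr

__all__ = [
    "ProportionCounts",
    "ConcordanceReport",
    "SelectionPressureResult",
    "binomial_lower_tail",
    "selection_pressure_tests",
    "concordance_suite",
    "GENOME_WIDE_DOWN_PROPORTION",
]

#: whole-genome reference proportion of affinity-reducing regulatory SNPs
#: (the cited 2:1 reducing-vs-increasing ratio)
GENOME_WIDE_DOWN_PROPORTION = 2.0 / 3.0


@dataclass(frozen=True)
class ProportionCounts:
    k: int
    n: int
    p0: float

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValueError("need 0 <= k <= n")
        if not 0 <= self.p0 <= 1:
            raise ValueError("need 0 <= p0 <= 1")


def binomial_lower_tail(k: int, n: int, p: float) -> float:
    """Exact P(X <= k) for X ~ Binomial(n, p), computed in log space."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < p < 1:
        raise ValueError(f"degenerate binomial parameter p={p}")
    i = np.arange(0, k + 1)
    log_terms = (
        gammaln(n + 1)
        - gammaln(i + 1)
        - gammaln(n - i + 1)
        + i * math.log(p)
        + (n - i) * math.log1p(-p)
    )
    return float(min(1.0, math.exp(logsumexp(log_terms))))


@dataclass(frozen=True)
class SelectionPressureResult:
    """One-sided deficit tests of expression-decreasing candidates."""

    p_vs_other: float
    p_vs_genome: float
    p_fisher_vs_other: float
    counts_familial: ProportionCounts
    counts_other: ProportionCounts


def selection_pressure_tests(summary) -> SelectionPressureResult:
    """Binomial lower-tail tests on a :class:`~promaff.marker_catalog.CountsSummary`.

    The familial-gene group's decrease count is tested against (a) the
    other-diseases group's observed decrease proportion treated as a fixed
    binomial p, and (b) the genome-wide two-thirds reference.  A Fisher
    exact 2x2 companion value is reported for transparency.
    """
    if summary.n_candidates_familial == 0 or summary.n_significant_other == 0:
        raise ValueError("selection-pressure tests need non-zero group sizes")
    p_other = summary.n_decrease_other / summary.n_significant_other
    k, n = summary.n_decrease_familial, summary.n_candidates_familial
    p_vs_other = binomial_lower_tail(k, n, p_other)
    p_vs_genome = binomial_lower_tail(k, n, GENOME_WIDE_DOWN_PROPORTION)
    table = [
        [k, n - k],
        [summary.n_decrease_other, summary.n_significant_other - summary.n_decrease_other],
    ]
    _, p_fisher = fisher_exact(table, alternative="less")
    return SelectionPressureResult(
        p_vs_other=p_vs_other,
        p_vs_genome=p_vs_genome,
        p_fisher_vs_other=float(p_fisher),
        counts_familial=ProportionCounts(k, n, GENOME_WIDE_DOWN_PROPORTION),
        counts_other=ProportionCounts(
            summary.n_decrease_other, summary.n_significant_other, p_other
        ),
    )


@dataclass(frozen=True)
class ConcordanceReport:
    r: float
    R: float
    tau: float
    gamma: float
    chi2: float
    p_fisher: float
    n_pairs: int


def _concordant_discordant(x: Sequence[float], y: Sequence[float]) -> tuple[int, int]:
    c = d = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            s = (x[i] - x[j]) * (y[i] - y[j])
            if s > 0:
                c += 1
            elif s < 0:
                d += 1
    return c, d


def _median_split_table(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    mx, my = np.median(x), np.median(y)
    hi_x, hi_y = x > mx, y > my
    return np.array(
        [
            [int(np.sum(hi_x & hi_y)), int(np.sum(hi_x & ~hi_y))],
            [int(np.sum(~hi_x & hi_y)), int(np.sum(~hi_x & ~hi_y))],
        ]
    )


def concordance_suite(pairs: Sequence[tuple[float, float]]) -> ConcordanceReport:
    """Predicted-vs-measured agreement statistics.

    r is the Pearson linear correlation, R Spearman's rank correlation, tau
    Kendall's tau-b, gamma the Goodman-Kruskal ratio (C - D)/(C + D) from
    brute-force pair counting, and chi2/p_fisher are evaluated on the 2x2
    table obtained by splitting each axis at its median.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in pairs")
    for name, v in (("predicted", x), ("measured", y)):
        if np.ptp(v) == 0:
            raise ValueError(f"correlation undefined: zero variance on {name} axis")
    r = float(pearsonr(x, y).statistic)
    big_r = float(spearmanr(x, y).statistic)
    tau = float(kendalltau(x, y).statistic)  # tau-b, handles ties
    c, d = _concordant_discordant(x, y)
    gamma = 0.0 if c + d == 0 else (c - d) / (c + d)
    table = _median_split_table(x, y)
    a, b = table[0]
    cc, dd = table[1]
    n = table.sum()
    denom = (a + b) * (cc + dd) * (a + cc) * (b + dd)
    chi2 = float(n * (a * dd - b * cc) ** 2 / denom) if denom else float("nan")
    _, p_fisher = fisher_exact(table)
    return ConcordanceReport(
        r=r,
        R=big_r,
        tau=tau,
        gamma=float(gamma),
        chi2=chi2,
        p_fisher=float(p_fisher),
        n_pairs=len(pairs),
    )
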