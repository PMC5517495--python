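"""Decision layer: Z statistic, significance level, A-E rank, direction call.

A pair of affinity estimates is compared with a Z statistic (absolute
difference of ln K_D over the root of the summed squared standard
deviations), converted to a two-sided normal tail probability, bucketed
into ranks A (strongest) through E (insignificant), and mapped to an
expression-direction call: a K_D increase means lower TBP affinity and
hence lower expected expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .affinity_model import (
    AffinityEstimate,
    ModelCoefficients,
    ModelTables,
    estimate_affinity,
)

__all__ = [
    "ComparisonResult",
    "z_score",
    "alpha_from_z",
    "rank_from_alpha",
    "compare_alleles",
    "RANK_THRESHOLDS",
]

#: rank buckets: alpha <= threshold, tried best-first
RANK_THRESHOLDS = (("A", 1e-6), ("B", 1e-3), ("C", 1e-2), ("D", 0.05))

OVER = "overexpression"
UNDER = "underexpression"
INSIGNIFICANT = "insignificant"

# smallest positive normal float: keeps alpha strictly positive even for
# extreme Z where the normal tail underflows
_ALPHA_FLOOR = 5e-324


@dataclass(frozen=True)
class ComparisonResult:
    z: float
    alpha: float
    decision: str
    rank: str
    delta_ln_kd: float


def z_score(est_wt: AffinityEstimate, est_minor: AffinityEstimate) -> float:
    """|delta ln K_D| over the root of the sum of squared SDs; symmetric."""
    if est_wt.sd <= 0 or est_minor.sd <= 0:
        raise ValueError("standard deviations must be positive")
    return abs(est_minor.ln_kd - est_wt.ln_kd) / math.hypot(est_wt.sd, est_minor.sd)


def alpha_from_z(z: float) -> float:
    """Two-sided standard-normal tail probability of |Z| >= z."""
    if z < 0:
        raise ValueError("z must be non-negative")
    return max(2.0 * float(norm.sf(z)), _ALPHA_FLOOR)


def rank_from_alpha(alpha: float) -> str:
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    for rank, threshold in RANK_THRESHOLDS:
        if alpha <= threshold:
            return rank
    return "E"


def compare_alleles(
    seq_wt: str,
    seq_minor: str,
    coeffs: ModelCoefficients,
    tables: ModelTables | None = None,
) -> ComparisonResult:
    """Full decision for one wt/minor sequence pair."""
    est_wt = estimate_affinity(seq_wt, coeffs, tables)
    est_minor = estimate_affinity(seq_minor, coeffs, tables)
    return compare_estimates(est_wt, est_minor)


def compare_estimates(
    est_wt: AffinityEstimate, est_minor: AffinityEstimate
) -> ComparisonResult:
    z = z_score(est_wt, est_minor)
    alpha = alpha_from_z(z)
    rank = rank_from_alpha(alpha)
    delta = est_minor.ln_kd - est_wt.ln_kd
    if rank == "E":
        decision = INSIGNIFICANT
    elif delta > 0:
        decision = UNDER  # higher K_D: lower affinity, lower expression
    else:
        decision = OVER
    return ComparisonResult(z=z, alpha=alpha, decision=decision, rank=rank, delta_ln_kd=delta)
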