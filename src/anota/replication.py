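"""Replication adjustment: from n participants x k pairs to an effective N.

In a replicated design each participant answers k stimulus pairs, giving
n*k response pairs — but those pairs are not independent when participants
differ systematically in their answering behaviour.  The adjustment factor
C converts the raw count into an effective sample size

    N_effective = n * k / C,          1 <= C <= k.

C is estimated as the cluster-sampling design effect of the per-participant
proportion of "A" answers (x_i out of m = 2k trials, pooling both stimulus
classes):

    C_raw = m * sum_i (p_i - p_bar)^2 / ((n - 1) * p_bar * (1 - p_bar))

which is the moment estimator of 1 + (m - 1)*rho with rho the
intra-participant correlation of binary answers.  C_raw below 1 is clamped
to 1 (no penalty), above k to k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReplicationAdjustment",
    "adjustment_C",
    "estimate_adjustment",
    "effective_N",
    "required_participants",
]


@dataclass(frozen=True)
class ReplicationAdjustment:
    """Adjustment factor C with the design sizes it links."""

    n: int
    k: int
    C: float
    N_effective: float
    rho: float  # estimated intra-participant correlation (from unclamped C)

    def __post_init__(self):
        assert 1.0 <= self.C <= self.k or self.k == 1


def _raw_design_effect(x: np.ndarray, m: int) -> float:
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("at least two participants required to estimate C")
    if m < 2:
        raise ValueError("m (trials per participant) must be >= 2")
    if np.any((x < 0) | (x > m)):
        raise ValueError("per-participant counts must lie in [0, m]")
    p_i = x / m
    p_bar = p_i.mean()
    if p_bar in (0.0, 1.0):
        return 0.0  # no variance anywhere: behaves as C = 1 after clamping
    return float(m * np.sum((p_i - p_bar) ** 2) / ((n - 1) * p_bar * (1 - p_bar)))


def adjustment_C(x, m: int) -> float:
    """Adjustment factor C from per-participant "A"-answer counts.

    Parameters
    ----------
    x : sequence of int
        Number of "A" answers per participant, each out of ``m`` trials.
    m : int
        Trials per participant, 2k in a paired design with k pairs.

    Returns the design-effect estimate clamped to [1, k] with k = m / 2.
    """
    if m % 2:
        raise ValueError("m must be even (2 trials per stimulus pair)")
    k = m // 2
    raw = _raw_design_effect(np.asarray(x), m)
    return float(min(max(raw, 1.0), k))


def estimate_adjustment(x, k: int) -> ReplicationAdjustment:
    """Full adjustment summary from per-participant counts and pair count k."""
    x = np.asarray(x)
    m = 2 * k
    raw = _raw_design_effect(x, m)
    C = float(min(max(raw, 1.0), k)) if k > 1 else 1.0
    n = int(x.size)
    return ReplicationAdjustment(
        n=n, k=k, C=C, N_effective=n * k / C,
        rho=(raw - 1) / (m - 1),
    )


def effective_N(n: int, k: int, C: float) -> float:
    """Effective number of independent response pairs, n * k / C."""
    if n < 1 or k < 1:
        raise ValueError("n and k must be >= 1")
    if C < 1:
        raise ValueError("C must be >= 1")
    return n * k / C


def required_participants(N_required: int, k: int, C: float) -> int:
    """Participants needed so that n * k / C reaches N_required (ceiling)."""
    if N_required < 1 or k < 1:
        raise ValueError("N_required and k must be >= 1")
    if C < 1:
        raise ValueError("C must be >= 1")
    return math.ceil(C * N_required / k)
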