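"""Power and minimum sample size for the paired A-Not A McNemar design.

A design is specified by the expected proportions of the two discordant
response patterns, p_b and p_c (proportions of the effective sample size N),
or equivalently by the odds ratio OR = p_b / p_c together with the
proportion of discordant pairs p_D = p_b + p_c.

Three methods are implemented, in increasing fidelity and cost:

* Miettinen's normal approximation (closed form in both directions).
  Writing psi = p_b + p_c and 2*Delta = p_c - p_b,

      power = Phi( (-z_{1-a} * psi + sqrt(N*psi) * |2 Delta|)
                   / sqrt(psi^2 - 4 Delta^2) )

  and the sample size solves this for N exactly (ceiling rounding).

* Bennett & Underwood's noncentral chi-square approximation:
  power = P( X^2_1(lambda) > k_{1-a} ) with lambda = 2 N Delta^2 / p,
  p = (p_b + p_c)/2, and k_{1-a} the central chi-square critical value of
  the one-tailed test (quantile at 1 - 2*alpha).  The sample size is found
  by numeric inversion (the formula cannot be solved for N).

* Unconditional exact power of the one-tailed exact conditional binomial
  McNemar test: the number of discordant pairs n_D is Binomial(N, p_D);
  conditional on n_D the dominant discordant count is
  Binomial(n_D, max(p_b,p_c)/p_D) and the (non-randomized, conservative)
  test rejects when it reaches the smallest critical count whose null
  (p = 1/2) tail probability is <= alpha.

All formulas are direction-symmetric: they are evaluated with |p_c - p_b|,
giving the power to detect the dominant discordant pattern whichever way
the labels point.  The printed forms are one-tailed; a two-tailed variant
is offered by substituting alpha/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DesignSpec",
    "PowerResult",
    "from_or_pd",
    "miettinen_power",
    "miettinen_n",
    "bu_power",
    "bu_n",
    "exact_power",
    "exact_n",
    "sample_size_grid",
    "DEFAULT_GRID",
]


def from_or_pd(OR: float, p_D: float) -> tuple:
    """Convert (odds ratio, proportion of discordant pairs) to (p_b, p_c).

    p_b = p_D * OR / (1 + OR) and p_c = p_D / (1 + OR), so that
    p_b / p_c = OR and p_b + p_c = p_D.
    """
    if OR <= 0:
        raise ValueError("OR must be positive")
    if not 0 < p_D < 1:
        raise ValueError("p_D must be in (0, 1)")
    return p_D * OR / (1 + OR), p_D / (1 + OR)


@dataclass(frozen=True)
class DesignSpec:
    """Planning parameters for a paired A-Not A McNemar design."""

    p_b: float
    p_c: float
    alpha: float = 0.05
    target_power: float = 0.8
    tails: str = "one"

    def __post_init__(self):
        if not (self.p_b > 0 and self.p_c > 0):
            raise ValueError("p_b and p_c must be positive")
        if self.p_b + self.p_c > 1:
            raise ValueError("p_b + p_c must not exceed 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must be in (0, 1)")
        if self.tails not in ("one", "two"):
            raise ValueError("tails must be 'one' or 'two'")

    @classmethod
    def from_or_pd(cls, OR: float, p_D: float, **kw) -> "DesignSpec":
        p_b, p_c = from_or_pd(OR, p_D)
        return cls(p_b=p_b, p_c=p_c, **kw)

    @property
    def psi(self) -> float:
        """p_b + p_c, the expected proportion of discordant pairs."""
        return self.p_b + self.p_c

    @property
    def p_D(self) -> float:
        return self.psi

    @property
    def delta(self) -> float:
        """Half the absolute discordant-proportion difference, |p_c - p_b| / 2."""
        return abs(self.p_c - self.p_b) / 2

    @property
    def odds_ratio(self) -> float:
        return self.p_b / self.p_c

    def _alpha_one_sided(self) -> float:
        return self.alpha if self.tails == "one" else self.alpha / 2


@dataclass(frozen=True)
class PowerResult:
    power: float
    N: int
    method: str

    def __post_init__(self):
        assert 0.0 <= self.power <= 1.0
        assert self.N >= 1


def miettinen_power(spec: DesignSpec, N: int) -> float:
    """Normal-approximation power at effective sample size N."""
    if N < 1:
        raise ValueError("N must be >= 1")
    psi = spec.psi
    two_delta = 2 * spec.delta
    denom_sq = psi**2 - two_delta**2
    if denom_sq <= 0:
        raise ValueError("degenerate design: psi^2 <= (2*Delta)^2")
    z_a = stats.norm.ppf(1 - spec._alpha_one_sided())
    arg = (-z_a * psi + math.sqrt(N * psi) * two_delta) / math.sqrt(denom_sq)
    return float(stats.norm.cdf(arg))


def miettinen_n(spec: DesignSpec) -> int:
    """Closed-form minimum N reaching the target power (ceiling rounding)."""
    psi = spec.psi
    two_delta = 2 * spec.delta
    if two_delta == 0:
        raise ValueError("p_b = p_c: no effect to detect")
    denom_sq = psi**2 - two_delta**2
    if denom_sq <= 0:
        raise ValueError("degenerate design: psi^2 <= (2*Delta)^2")
    z_a = stats.norm.ppf(1 - spec._alpha_one_sided())
    z_b = stats.norm.ppf(spec.target_power)
    N = (z_a * psi + z_b * math.sqrt(denom_sq)) ** 2 / (psi * two_delta**2)
    return math.ceil(N)


def bu_power(spec: DesignSpec, N: int) -> float:
    """Noncentral chi-square power at effective sample size N.

    Noncentrality lambda = 2 N Delta^2 / p with p = (p_b + p_c) / 2; the
    one-tailed critical value is the central chi-square quantile at
    1 - 2*alpha (at alpha = .05: 2.71, the 90th percentile).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    p = spec.psi / 2
    if p <= 0:
        raise ValueError("p must be positive")
    lam = 2 * N * spec.delta**2 / p
    a1 = spec._alpha_one_sided()
    crit = stats.chi2.ppf(1 - 2 * a1, 1)
    return float(stats.ncx2.sf(crit, 1, lam))


def _invert_power(power_fn, spec: DesignSpec, n_max: int = 10_000_000) -> int:
    """Smallest integer N with power_fn(spec, N) >= target, by bracket + bisection."""
    target = spec.target_power
    lo, hi = 1, 2
    while power_fn(spec, hi) < target:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise ValueError("required N exceeds the search cap")
    while lo < hi:
        mid = (lo + hi) // 2
        if power_fn(spec, mid) >= target:
            hi = mid
        else:
            lo = mid + 1
    return lo


def bu_n(spec: DesignSpec) -> int:
    """Minimum N under the noncentral chi-square approximation (numeric inversion)."""
    if spec.delta == 0:
        raise ValueError("p_b = p_c: no effect to detect")
    return _invert_power(bu_power, spec)


def exact_power(spec: DesignSpec, N: int, max_n: int = 20_000) -> float:
    """Unconditional exact power of the one-tailed exact McNemar test.

    Enumerates the Binomial(N, p_D) distribution of the discordant count and,
    for each value n_D, the probability that the dominant discordant count
    (Binomial(n_D, p_dom)) reaches the smallest critical count whose
    Binomial(n_D, 1/2) upper tail is <= alpha.  The conditional test is
    non-randomized, hence conservative.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if N > max_n:
        raise ValueError(
            f"N = {N} exceeds the enumeration cap ({max_n}); "
            "use miettinen_power or bu_power instead"
        )
    p_D = spec.psi
    p_dom = max(spec.p_b, spec.p_c) / p_D
    alpha = spec._alpha_one_sided()
    n_d = np.arange(N + 1)
    weights = stats.binom.pmf(n_d, N, p_D)
    # smallest critical count per n_D: isf returns the largest count with
    # sf > alpha, so the critical count is one above it
    crit = stats.binom.isf(alpha, n_d, 0.5) + 1
    # guard the exact-boundary case: sf at crit-1 must be <= alpha
    too_low = stats.binom.sf(crit - 2, n_d, 0.5) <= alpha
    crit = np.where(too_low, crit - 1, crit)
    reject_prob = stats.binom.sf(crit - 1, n_d, p_dom)
    reject_prob = np.where(crit > n_d, 0.0, reject_prob)  # no attainable region
    return float(np.sum(weights * reject_prob))


def exact_n(spec: DesignSpec, max_n: int = 20_000) -> int:
    """Smallest N whose unconditional exact power reaches the target.

    Exact power is a sawtooth in N (the critical count jumps), so the scan
    walks upward from a conservative start rather than bisecting.
    """
    start = 2
    try:
        start = max(2, int(0.5 * miettinen_n(spec)))
    except ValueError:
        pass
    # step back if the start already satisfies the target
    N = start
    while N > 2 and exact_power(spec, N - 1, max_n) >= spec.target_power:
        N -= 1
    while exact_power(spec, N, max_n) < spec.target_power:
        N += 1
        if N > max_n:
            raise ValueError("required N exceeds the enumeration cap")
    return N


# the planning grid: odds ratios by proportions of discordant pairs
DEFAULT_GRID = {
    "OR": (5, 4, 3, 2, 1.5),
    "p_D": (0.2, 0.3, 0.4, 0.5, 0.6),
}


def sample_size_grid(alpha: float = 0.05, target_power: float = 0.8,
                     methods: tuple = ("miettinen", "bu"),
                     OR_values: tuple = DEFAULT_GRID["OR"],
                     p_D_values: tuple = DEFAULT_GRID["p_D"]):
    """Required-N table over a grid of (OR, p_D) planning settings.

    Returns a pandas DataFrame with one row per (p_D, OR) cell carrying the
    implied p_b, p_c and the minimum N per requested method
    ("miettinen", "bu", "exact").
    """
    import pandas as pd

    solvers = {"miettinen": miettinen_n, "bu": bu_n, "exact": exact_n}
    rows = []
    for p_D in p_D_values:
        for OR in OR_values:
            p_b, p_c = from_or_pd(OR, p_D)
            spec = DesignSpec(p_b=round(p_b, 4), p_c=round(p_c, 4),
                              alpha=alpha, target_power=target_power)
            row = {"p_D": p_D, "OR": OR, "p_b": spec.p_b, "p_c": spec.p_c}
            for m in methods:
                row[f"N_{m}"] = solvers[m](spec)
            rows.append(row)
    return pd.DataFrame(rows)
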