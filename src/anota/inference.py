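"""McNemar's test of allocation behaviour against chance.

Under the null hypothesis the probability of answering "A" is the same for
A stimuli and Not-A stimuli, which reduces to equality of the two discordant
pattern frequencies b and c.  Only those discordant counts enter the test.

The asymptotic statistic is (b - c)^2 / (b + c), chi-square with df = 1; the
exact test conditions on b + c and refers c to a Binomial(b + c, 1/2).  The
exact test is the default and the preferred method.  The one-tailed
alternative is that correct allocations dominate (p_c > p_b); when the data
go the other way (c <= b) the result carries ``direction_ok=False`` and a
warning, since reversed allocation means participants systematically swapped
the two categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .io_tabulate import PatternCounts

__all__ = [
    "TestResult",
    "mcnemar_statistic",
    "mcnemar_test",
    "critical_value",
    "UndefinedStatisticError",
]


class UndefinedStatisticError(ZeroDivisionError):
    """No discordant pairs: the McNemar statistic is undefined."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of a McNemar test.

    ``direction_ok`` flags whether the correct-allocation pattern dominates
    (c > b); a one-tailed p with ``direction_ok=False`` should not be taken
    as evidence of discrimination ability.
    """

    p_value: float
    tails: str
    method: str
    direction_ok: bool
    statistic: Optional[float] = None
    df: int = 1

    def __post_init__(self):
        assert 0.0 <= self.p_value <= 1.0
        assert self.statistic is None or self.statistic >= 0


def mcnemar_statistic(b: int, c: int, continuity: bool = False) -> float:
    """Chi-square statistic (b - c)^2 / (b + c), df = 1.

    With ``continuity=True`` the Edwards-corrected form
    (|b - c| - 1)^2 / (b + c) is returned (0 when b = c).
    """
    b, c = int(b), int(c)
    if b < 0 or c < 0:
        raise ValueError("counts must be non-negative")
    if b + c == 0:
        raise UndefinedStatisticError("no discordant pairs: b + c = 0")
    if continuity:
        return (max(abs(b - c) - 1, 0)) ** 2 / (b + c)
    return (b - c) ** 2 / (b + c)


def _exact_p(b: int, c: int, tails: str) -> float:
    n = b + c
    if tails == "one":
        # alternative: correct pattern dominates, P(X >= c) under Binomial(n, 1/2)
        return float(stats.binom.sf(c - 1, n, 0.5))
    # two-tailed: double the smaller tail, capped at 1
    lo, hi = min(b, c), max(b, c)
    tail = min(float(stats.binom.cdf(lo, n, 0.5)), float(stats.binom.sf(hi - 1, n, 0.5)))
    return min(1.0, 2.0 * tail)


def mcnemar_test(pc: PatternCounts, tails: str = "one", method: str = "exact") -> TestResult:
    """Test H0: p_b = p_c (chance-level allocation).

    Parameters
    ----------
    pc : PatternCounts
        Tabulated pattern frequencies; only b and c enter the test.
    tails : {"one", "two"}
        One-tailed tests the alternative p_c > p_b.
    method : {"exact", "approximate", "continuity"}
        "exact" (default, preferred) refers c to Binomial(b+c, 1/2);
        the chi-square approximations require b + c > 0.
    """
    if tails not in ("one", "two"):
        raise ValueError(f"tails must be 'one' or 'two', got {tails!r}")
    b, c = pc.b, pc.c
    direction_ok = c > b
    if tails == "one" and not direction_ok:
        warnings.warn(
            "one-tailed test requested but the correct-allocation pattern does "
            "not dominate (c <= b): possible reversed allocation behaviour",
            stacklevel=2,
        )

    if method == "exact":
        if b + c == 0:
            # every pair concordant: no evidence either way
            return TestResult(p_value=1.0, tails=tails, method=method,
                              direction_ok=direction_ok, statistic=None)
        return TestResult(p_value=_exact_p(b, c, tails), tails=tails,
                          method=method, direction_ok=direction_ok, statistic=None)

    if method in ("approximate", "continuity"):
        stat = mcnemar_statistic(b, c, continuity=(method == "continuity"))
        if tails == "two":
            p = float(stats.chi2.sf(stat, 1))
        else:
            # signed normal deviate so that c < b gives p > 1/2; the
            # continuity correction replaces c by c - 1/2 in P(X >= c)
            shift = 1 if method == "continuity" else 0
            z = (c - b - shift) / np.sqrt(b + c)
            p = float(stats.norm.sf(z))
        return TestResult(p_value=p, tails=tails, method=method,
                          direction_ok=direction_ok, statistic=stat)

    raise ValueError(f"unknown method {method!r}")


def critical_value(alpha: float, tails: str = "two") -> float:
    """Chi-square (df = 1) critical value for the McNemar statistic.

    Two-tailed at alpha = .05 gives 3.84; a one-tailed test uses half the
    level, so alpha = .05 one-tailed gives the quantile at p <= .025, 5.02.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if tails == "two":
        return float(stats.chi2.ppf(1 - alpha, 1))
    if tails == "one":
        return float(stats.chi2.ppf(1 - alpha / 2, 1))
    raise ValueError(f"tails must be 'one' or 'two', got {tails!r}")
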