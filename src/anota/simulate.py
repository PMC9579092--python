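"""Synthetic observers and Monte-Carlo validation.

The generator implements the equal-variance Gaussian observer that underlies
the d'/criterion analysis: on each trial the stimulus produces a normal
evidence value (mean d' for A stimuli, mean 0 for Not-A, unit variance) and
the observer answers "A" when the evidence exceeds the threshold
d'/2 + c.  With criterion c = 0 the threshold sits midway between the two
evidence distributions and the observer is unbiased; c > 0 shifts it upward,
producing a "Not A" tendency.  Hence

    p_hit = Phi(d'/2 - c),        p_fa = Phi(-d'/2 - c),

and plugging these into the d'/c estimators recovers the generating
parameters exactly.

Participant heterogeneity is modelled by drawing each participant's
(d'_i, c_i) from normal distributions around the population values.  The two
trials of a pair are conditionally independent given the participant's
parameters, so the joint pattern probabilities of a pair factorize:

    p_a = p_hit * p_fa            ("A" twice)
    p_b = (1 - p_hit) * p_fa      (both wrong)
    p_c = p_hit * (1 - p_fa)      (both correct)
    p_d = (1 - p_hit)*(1 - p_fa)  ("Not A" twice)

The Monte-Carlo power routine exploits the same factorization: instead of
simulating individual trials it draws each participant's pattern counts from
the implied multinomial, which is distribution-identical and much faster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .io_tabulate import ResponseMatrix

__all__ = [
    "ObserverConfig",
    "MCPowerResult",
    "hit_fa_probs",
    "pattern_probs_from_observer",
    "observer_from_discordant",
    "simulate_responses",
    "simulate_pattern_counts",
    "mc_power",
    "mc_power_design",
]


@dataclass(frozen=True)
class ObserverConfig:
    """Population observer and design sizes for the generator.

    ``sd_between_dprime`` and ``sd_between_criterion`` scale the normal
    participant-level heterogeneity of sensitivity and criterion; zero gives
    an exchangeable population in which all n*k response pairs are iid.
    """

    n: int
    k: int
    d_prime_true: float = 1.0
    criterion_true: float = 0.0
    sd_between_dprime: float = 0.0
    sd_between_criterion: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n < 1 or self.k < 1:
            raise ValueError("n and k must be >= 1")
        if self.sd_between_dprime < 0 or self.sd_between_criterion < 0:
            raise ValueError("heterogeneity scales must be >= 0")


def hit_fa_probs(d_prime: float, criterion: float) -> tuple:
    """Hit and false-alarm probabilities of the Gaussian observer."""
    p_hit = float(stats.norm.cdf(d_prime / 2 - criterion))
    p_fa = float(stats.norm.cdf(-d_prime / 2 - criterion))
    return p_hit, p_fa


def pattern_probs_from_observer(d_prime: float, criterion: float) -> tuple:
    """Analytic probabilities (p_a, p_b, p_c, p_d) of the four pair patterns."""
    h, f = hit_fa_probs(d_prime, criterion)
    return (h * f, (1 - h) * f, h * (1 - f), (1 - h) * (1 - f))


def observer_from_discordant(p_b: float, p_c: float) -> tuple:
    """Invert the observer model from the two discordant pattern probabilities.

    Solves p_b = (1 - h)*f, p_c = h*(1 - f) for (h, f) in closed form
    (taking the root with h <= the complementary solution) and maps to
    (d_prime, criterion).  Useful for driving Monte-Carlo validation at a
    planning design given by (p_b, p_c).
    """
    if not (0 < p_b < 1 and 0 < p_c < 1) or p_b + p_c >= 1:
        raise ValueError("p_b, p_c must be in (0,1) with p_b + p_c < 1")
    s = p_c - p_b
    D = p_b + p_c
    disc = (1 + s) ** 2 - 2 * (s + D)
    if disc < 0:
        raise ValueError("no observer attains these pattern probabilities")
    h = ((1 + s) - np.sqrt(disc)) / 2
    f = h - s
    if not (0 < h < 1 and 0 < f < 1):
        raise ValueError("no observer attains these pattern probabilities")
    zh, zf = stats.norm.ppf(h), stats.norm.ppf(f)
    return float(zh - zf), float(-0.5 * (zh + zf))


def _participant_params(cfg: ObserverConfig, rng: np.random.Generator,
                        size: tuple) -> tuple:
    d = cfg.d_prime_true + cfg.sd_between_dprime * rng.standard_normal(size)
    c = cfg.criterion_true + cfg.sd_between_criterion * rng.standard_normal(size)
    return d, c


def simulate_responses(cfg: ObserverConfig) -> ResponseMatrix:
    """Generate a full trial-level response matrix from the observer model.

    Column layout follows the convention of sorting by stimulus class: the k
    A-stimulus columns (odd stimulus numbers) first, then the k Not-A columns
    (even numbers); pair j joins columns j and k + j.  Deterministic under a
    fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n, cfg.k
    d_i, c_i = _participant_params(cfg, rng, (n, 1))
    threshold = d_i / 2 + c_i
    evidence_A = rng.standard_normal((n, k)) + d_i
    evidence_N = rng.standard_normal((n, k))
    resp_A = (evidence_A > threshold).astype(np.int8)
    resp_N = (evidence_N > threshold).astype(np.int8)
    responses = np.hstack([resp_A, resp_N])
    names = [f"Stim{2 * j + 1:02d}_A" for j in range(k)] + \
            [f"Stim{2 * j + 2:02d}_NotA" for j in range(k)]
    return ResponseMatrix(
        participant_ids=[f"P{i + 1:04d}" for i in range(n)],
        responses=responses,
        pair_index=[(j, k + j) for j in range(k)],
        column_names=names,
    )


def simulate_pattern_counts(cfg: ObserverConfig, reps: int,
                            rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Pooled pattern counts (a, b, c, d) for ``reps`` replicate studies.

    Uses the multinomial shortcut: per participant the k pair patterns are
    iid multinomial draws with the participant's analytic pattern
    probabilities, which matches the trial-level generator in distribution.
    Returns an array of shape (reps, 4).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n, cfg.k
    if cfg.sd_between_dprime == 0 and cfg.sd_between_criterion == 0:
        probs = np.array(pattern_probs_from_observer(cfg.d_prime_true,
                                                     cfg.criterion_true))
        return rng.multinomial(n * k, probs, size=reps)
    d_i, c_i = _participant_params(cfg, rng, (reps, n))
    h = stats.norm.cdf(d_i / 2 - c_i)
    f = stats.norm.cdf(-d_i / 2 - c_i)
    probs = np.stack([h * f, (1 - h) * f, h * (1 - f), (1 - h) * (1 - f)],
                     axis=-1)
    counts = rng.multinomial(k, probs)
    return counts.sum(axis=1)


@dataclass(frozen=True)
class MCPowerResult:
    """Empirical rejection rate with its binomial standard error."""

    power: float
    se: float
    reps: int


def _reject_exact_one(b: np.ndarray, c: np.ndarray, alpha: float) -> np.ndarray:
    nd = b + c
    p = stats.binom.sf(c - 1, np.maximum(nd, 1), 0.5)
    p = np.where(nd == 0, 1.0, p)
    return p <= alpha


def _reject(b: np.ndarray, c: np.ndarray, alpha: float, tails: str,
            method: str) -> np.ndarray:
    nd = b + c
    if method == "exact":
        if tails == "one":
            return _reject_exact_one(b, c, alpha)
        nd_safe = np.maximum(nd, 1)
        lo = np.minimum(b, c)
        hi = np.maximum(b, c)
        tail = np.minimum(stats.binom.cdf(lo, nd_safe, 0.5),
                          stats.binom.sf(hi - 1, nd_safe, 0.5))
        p = np.where(nd == 0, 1.0, np.minimum(1.0, 2 * tail))
        return p <= alpha
    if method == "approximate":
        stat = np.where(nd > 0, (b - c) ** 2 / np.maximum(nd, 1), 0.0)
        if tails == "two":
            p = stats.chi2.sf(stat, 1)
        else:
            z = (c - b) / np.sqrt(np.maximum(nd, 1))
            p = stats.norm.sf(np.where(nd > 0, z, 0.0))
        return (p <= alpha) & (nd > 0)
    raise ValueError(f"unknown method {method!r}")


def mc_power_design(spec, N: int, alpha: float = None, tails: str = None,
                    method: str = "exact", reps: int = 1000,
                    seed: Optional[int] = None,
                    ) -> MCPowerResult:
    """Empirical power at a planning design, bypassing the observer model.

    Draws pooled pattern counts from Multinomial(N, (p_a, p_b, p_c, p_d))
    with the concordant remainder 1 - p_b - p_c split evenly between a and d
    (the test only sees b and c, so the split is immaterial).  This validates
    the analytic power formulas for designs an independent-trials observer
    cannot attain (high discordance at small odds ratios).
    """
    from .power import DesignSpec  # noqa: F401  (type of ``spec``)

    if reps < 100:
        raise ValueError("reps must be >= 100")
    alpha = spec.alpha if alpha is None else alpha
    tails = spec.tails if tails is None else tails
    rng = np.random.default_rng(seed)
    rest = (1 - spec.p_b - spec.p_c) / 2
    probs = np.array([rest, spec.p_b, spec.p_c, rest])
    counts = rng.multinomial(N, probs, size=reps)
    rejected = _reject(counts[:, 1], counts[:, 2], alpha, tails, method)
    p_hat = float(rejected.mean())
    return MCPowerResult(power=p_hat,
                         se=float(np.sqrt(p_hat * (1 - p_hat) / reps)),
                         reps=reps)


def mc_power(cfg: ObserverConfig, alpha: float = 0.05, tails: str = "one",
             method: str = "exact", reps: int = 1000,
             seed: Optional[int] = None) -> MCPowerResult:
    """Empirical power of the McNemar test under the observer model.

    Simulates ``reps`` studies of n participants x k pairs, applies the
    requested McNemar variant at level ``alpha`` to the pooled counts of
    each, and returns the rejection fraction with its binomial SE.
    Reproducible: ``seed`` overrides ``cfg.seed``.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    counts = simulate_pattern_counts(cfg, reps, rng)
    rejected = _reject(counts[:, 1], counts[:, 2], alpha, tails, method)
    p_hat = float(rejected.mean())
    return MCPowerResult(power=p_hat,
                         se=float(np.sqrt(p_hat * (1 - p_hat) / reps)),
                         reps=reps)
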