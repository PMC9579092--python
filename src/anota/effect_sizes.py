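"""Effect sizes for the paired A-Not A design.

Three families of effect size are computed:

* Cohen's w = sqrt(X^2 / N) from the McNemar statistic;
* the odds ratio OR = b / c of the discordant patterns;
* the signal-detection pair d' (sensitivity) and c (criterion), computed
  from the hit and false-alarm proportions under the equal-variance
  Gaussian model:

      d' = z(p_hits) - z(p_fas)
      c  = -1/2 * [z(p_hits) + z(p_fas)]

Proportions of exactly 0 or 1 would put the normal quantile at +-infinity;
they are substituted by 1/(2k) and 1 - 1/(2k) respectively (k = number of
stimulus pairs) before the z-transform.  Positive criterion c indicates a
tendency toward "Not A" answers (miss rate above false-alarm rate).

Benchmark classifications follow the conventional cut points for each
measure; the A-Not A and 2-AFC d' benchmark sets are *not* sqrt(2)
multiples of one another and are kept as two separate scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .io_tabulate import SDTCounts

__all__ = [
    "SDTSummary",
    "BENCHMARKS",
    "cohens_w",
    "odds_ratio",
    "correct_proportion",
    "dprime",
    "dprime_from_counts",
    "dprime_2afc_equivalent",
    "classify_effect",
    "summary_table",
]


@dataclass(frozen=True)
class SDTSummary:
    """Sensitivity and criterion with the quantities they were derived from."""

    p_hits: float
    p_fas: float
    p_hits_corr: float
    p_fas_corr: float
    z_hits: float
    z_fas: float
    d_prime: float
    criterion_c: float
    k: int


def cohens_w(statistic: float, N: int) -> float:
    """Cohen's w = sqrt(X^2 / N) for a chi-square statistic on N pairs."""
    if N <= 0:
        raise ValueError("N must be positive")
    if statistic < 0:
        raise ValueError("chi-square statistic must be non-negative")
    return math.sqrt(statistic / N)


def odds_ratio(b: int, c: int, correction: str = "none") -> float:
    """Discordant-pattern odds ratio OR = b / c.

    ``correction="haldane"`` adds 1/2 to both counts, allowing c = 0.
    """
    if b < 0 or c < 0:
        raise ValueError("counts must be non-negative")
    if correction == "haldane":
        return (b + 0.5) / (c + 0.5)
    if correction == "none":
        if c == 0:
            raise ZeroDivisionError(
                "c = 0 gives an infinite odds ratio; use correction='haldane'"
            )
        return b / c
    raise ValueError(f"unknown correction {correction!r}")


def correct_proportion(p: float, k: int) -> float:
    """Replace an extreme proportion by 1/(2k) or 1 - 1/(2k).

    Values strictly inside (0, 1) pass through unchanged; only exact 0 and
    exact 1 are substituted.
    """
    if not 0 <= p <= 1:
        raise ValueError("proportion outside [0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    if p == 0:
        return 1 / (2 * k)
    if p == 1:
        return 1 - 1 / (2 * k)
    return p


def dprime(p_hits: float, p_fas: float, k: int) -> SDTSummary:
    """Equal-variance d' and criterion c from hit / false-alarm proportions.

    Extreme proportions are corrected by the 1/(2k) substitution first; both
    d' and c are computed on the corrected values.
    """
    ph = correct_proportion(p_hits, k)
    pf = correct_proportion(p_fas, k)
    zh = float(stats.norm.ppf(ph))
    zf = float(stats.norm.ppf(pf))
    return SDTSummary(
        p_hits=p_hits, p_fas=p_fas, p_hits_corr=ph, p_fas_corr=pf,
        z_hits=zh, z_fas=zf,
        d_prime=zh - zf, criterion_c=-0.5 * (zh + zf), k=k,
    )


def dprime_from_counts(sdt: SDTCounts, k: int) -> SDTSummary:
    """Convenience wrapper computing d' directly from SDT counts."""
    return dprime(sdt.p_hits, sdt.p_fas, k)


def dprime_2afc_equivalent(dprime_anota: float) -> float:
    """Convert an A-Not A d' to the 2-AFC scale (factor sqrt(2), ~41% larger)."""
    return math.sqrt(2) * dprime_anota


# measure -> ordered (lower bound, label); a value gets the label of the
# highest bound it reaches (lower bound inclusive).  Values below the first
# bound are "none".
BENCHMARKS = {
    "w": ((0.1, "small"), (0.3, "medium"), (0.5, "large")),
    "OR": ((1.22, "small"), (1.86, "medium"), (3.0, "large")),
    "dprime_anota": ((0.0, "rather-small"), (0.74, "meaningful"), (1.81, "rather-large")),
    "dprime_2afc": ((0.5, "small"), (1.0, "medium"), (1.5, "large")),
}


def classify_effect(value: float, measure: str) -> str:
    """Classify an effect-size value against the benchmark scale for ``measure``.

    ``measure`` is one of ``"w"``, ``"OR"``, ``"dprime_anota"``,
    ``"dprime_2afc"``.  Boundaries belong to the larger category; the
    A-Not A d' scale additionally treats exactly 0 as "none" (no effect).
    """
    if measure not in BENCHMARKS:
        raise ValueError(f"unknown measure {measure!r}")
    label = "none"
    for bound, name in BENCHMARKS[measure]:
        if measure == "dprime_anota" and bound == 0.0:
            if value > bound:
                label = name
        elif value >= bound:
            label = name
    return label


def summary_table(rm):
    """Per-participant and pooled outcome summary as a DataFrame.

    One row per participant plus a final "pooled" row, each carrying the
    pattern counts, SDT counts, "A"-answer total, raw and corrected hit /
    false-alarm proportions, their z-transforms and the resulting d' and
    criterion c.  Write with ``df.to_csv(...)`` for the spreadsheet-style
    outcome report.
    """
    import pandas as pd

    from .io_tabulate import SDTCounts, tabulate_patterns

    per = tabulate_patterns(rm, "per_participant")
    rows = []
    items = list(per.items()) + [("pooled", sum(per.values(),
                                                next(iter(per.values())).__class__(0, 0, 0, 0)))]
    for pid, pc in items:
        sc = SDTCounts.from_patterns(pc)
        s = dprime(sc.p_hits, sc.p_fas, rm.k)
        rows.append({
            "participant": pid,
            "a": pc.a, "b": pc.b, "c": pc.c, "d": pc.d,
            "hits": sc.hits, "misses": sc.misses,
            "false_alarms": sc.false_alarms,
            "correct_rejections": sc.correct_rejections,
            "answers_A": sc.answers_A,
            "p_hits": s.p_hits, "p_fas": s.p_fas,
            "p_hits_corr": s.p_hits_corr, "p_fas_corr": s.p_fas_corr,
            "z_hits": s.z_hits, "z_fas": s.z_fas,
            "d_prime": s.d_prime, "criterion_c": s.criterion_c,
        })
    return pd.DataFrame(rows)
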