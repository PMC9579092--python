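"""Reading and tabulating paired A-Not A response matrices.

A paired A-Not A (yes-no) study presents each participant with k pairs of
stimuli; each pair contains one stimulus of class A and one of class Not A,
and every stimulus is answered "A" (coded 1) or "Not A" (coded 0).  The joint
answer to a pair falls into one of four patterns:

    a : "A" to both stimuli          (false alarm on the Not-A member)
    b : both answers wrong           (miss on A, false alarm on Not A)
    c : both answers correct         (hit on A, correct rejection on Not A)
    d : "Not A" to both stimuli      (miss on the A member)

The discordant patterns b and c carry all the information for the test of
allocation ability against chance; the margins of the pattern table recover
the classical hit / miss / false-alarm / correct-rejection counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ResponseMatrix",
    "PatternCounts",
    "SDTCounts",
    "ValidationError",
    "read_response_matrix",
    "write_response_matrix",
    "classify_pair",
    "tabulate_patterns",
    "sdt_counts",
    "answers_A_per_participant",
]


class ValidationError(ValueError):
    """Input data violates the response-matrix contract."""


# pattern labels in canonical order
PATTERNS = ("a", "b", "c", "d")

# (response to A stimulus, response to Not-A stimulus) -> pattern
_PATTERN_OF = {(1, 1): "a", (0, 1): "b", (1, 0): "c", (0, 0): "d"}


def classify_pair(response_to_A: int, response_to_NotA: int) -> str:
    """Classify one pair of binary answers into pattern a, b, c or d.

    ``response_to_A`` is the answer given to the A member of the pair and
    ``response_to_NotA`` the answer to the Not-A member, both coded
    1 = "A", 0 = "Not A".  The mapping is a bijection from {0,1}^2:
    (1,1) -> a, (0,1) -> b, (1,0) -> c, (0,0) -> d.
    """
    key = (int(response_to_A), int(response_to_NotA))
    if key[0] not in (0, 1) or key[1] not in (0, 1):
        raise ValidationError(f"responses must be 0 or 1, got {key}")
    return _PATTERN_OF[key]


@dataclass(frozen=True)
class PatternCounts:
    """Frequencies of the four paired response patterns.

    ``N = a + b + c + d`` is the effective sample size: the number of
    response pairs, n*k when tabulated from a full response matrix.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in PATTERNS:
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"pattern count {name} must be a non-negative integer, got {v}")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def p_b(self) -> float:
        return self.b / self.N

    @property
    def p_c(self) -> float:
        return self.c / self.N

    @property
    def p_discordant(self) -> float:
        """Proportion of discordant pairs, (b + c) / N."""
        return (self.b + self.c) / self.N

    def __add__(self, other: "PatternCounts") -> "PatternCounts":
        return PatternCounts(self.a + other.a, self.b + other.b,
                             self.c + other.c, self.d + other.d)


@dataclass(frozen=True)
class SDTCounts:
    """Classical signal-detection counts, the margins of the pattern table."""

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    @property
    def trials_per_class(self) -> int:
        return self.hits + self.misses

    @property
    def p_hits(self) -> float:
        return self.hits / self.trials_per_class

    @property
    def p_fas(self) -> float:
        return self.false_alarms / self.trials_per_class

    @property
    def answers_A(self) -> int:
        """Total "A" answers: hits plus false alarms."""
        return self.hits + self.false_alarms

    @classmethod
    def from_patterns(cls, pc: PatternCounts) -> "SDTCounts":
        # margins of the pattern table: hits = a+c, misses = b+d,
        # FAs = a+b, CRs = c+d
        return cls(hits=pc.a + pc.c, misses=pc.b + pc.d,
                   false_alarms=pc.a + pc.b, correct_rejections=pc.c + pc.d)


@dataclass
class ResponseMatrix:
    """Per-participant binary responses with explicit A / Not-A pair structure.

    ``responses`` is an n x 2k array of 0/1 answers; ``pair_index`` maps each
    of the k pairs to its (A column, Not-A column) positions in that array.
    """

    participant_ids: list
    responses: np.ndarray
    pair_index: list  # list of (A-column, NotA-column) integer tuples
    column_names: list = field(default_factory=list)

    def __post_init__(self):
        self.responses = np.asarray(self.responses)
        if self.responses.ndim != 2:
            raise ValidationError("responses must be a 2-D array")
        n, ncol = self.responses.shape
        if n < 1:
            raise ValidationError("at least one participant required")
        if len(self.participant_ids) != n:
            raise ValidationError("participant_ids length must match number of rows")
        if len(set(map(str, self.participant_ids))) != n:
            raise ValidationError("duplicate participant IDs")
        bad = ~np.isin(self.responses, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary cell at participant {self.participant_ids[r]!r}, "
                f"column {self._colname(c)}: {self.responses[r, c]!r}"
            )
        if ncol != 2 * len(self.pair_index):
            raise ValidationError("pair_index must cover all response columns exactly")
        cols = [c for pair in self.pair_index for c in pair]
        if sorted(cols) != list(range(ncol)):
            raise ValidationError("pair_index columns must partition the response columns")
        self.responses = self.responses.astype(np.int8)
        if not self.column_names:
            self.column_names = [f"col{j}" for j in range(ncol)]

    def _colname(self, j: int) -> str:
        return self.column_names[j] if self.column_names else f"col{j}"

    @property
    def n(self) -> int:
        """Number of participants."""
        return self.responses.shape[0]

    @property
    def k(self) -> int:
        """Number of stimulus pairs (replications)."""
        return len(self.pair_index)

    @property
    def N(self) -> int:
        """Effective number of response pairs, n * k."""
        return self.n * self.k


def _pairs_from_suffix(columns: list) -> list:
    """Pair the i-th ``_A`` column with the i-th ``_NotA`` column, in order."""
    a_cols = [j for j, c in enumerate(columns) if c.endswith("_A")]
    nota_cols = [j for j, c in enumerate(columns) if c.endswith("_NotA")]
    leftover = [c for j, c in enumerate(columns) if j not in a_cols and j not in nota_cols]
    if leftover:
        raise ValidationError(
            f"columns without _A/_NotA suffix under the suffix schema: {leftover}"
        )
    if len(a_cols) != len(nota_cols):
        raise ValidationError(
            f"unmatched pair suffixes: {len(a_cols)} '_A' columns vs "
            f"{len(nota_cols)} '_NotA' columns"
        )
    return list(zip(a_cols, nota_cols))


def _pairs_positional(ncol: int) -> list:
    """Columns 1..k are the A stimuli, k+1..2k the Not-A stimuli, paired in order."""
    k = ncol // 2
    return [(j, k + j) for j in range(k)]


def read_response_matrix(path, schema: str = "suffix") -> ResponseMatrix:
    """Read a response-matrix CSV.

    The file has one header row, a leading participant-ID column and 2k
    binary response columns.  ``schema`` selects how columns are grouped
    into A / Not-A pairs:

    - ``"suffix"`` (default): columns named ``*_A`` are A stimuli and
      ``*_NotA`` are Not-A stimuli; the i-th of each group (in file order)
      form a pair.
    - ``"positional"``: the first k response columns are the A stimuli, the
      last k the Not-A stimuli, paired in order.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if df.shape[1] < 3:
        raise ValidationError(
            "expected a participant-ID column plus at least 2 response columns"
        )
    if df.shape[0] < 1:
        raise ValidationError("no data rows")
    ids = df.iloc[:, 0].tolist()
    resp_df = df.iloc[:, 1:]
    ncol = resp_df.shape[1]
    if ncol % 2:
        raise ValidationError(f"odd number of response columns ({ncol})")
    columns = list(resp_df.columns)

    values = np.full(resp_df.shape, -1, dtype=np.int64)
    for j, col in enumerate(columns):
        for i, cell in enumerate(resp_df[col]):
            s = (cell or "").strip() if isinstance(cell, str) else cell
            if s in ("0", "1"):
                values[i, j] = int(s)
            else:
                raise ValidationError(
                    f"non-binary cell at row {i + 1} (participant {ids[i]!r}), "
                    f"column {col!r}: {cell!r}"
                )

    if schema == "suffix":
        pair_index = _pairs_from_suffix(columns)
    elif schema == "positional":
        pair_index = _pairs_positional(ncol)
    else:
        raise ValidationError(f"unknown schema {schema!r}")
    return ResponseMatrix(participant_ids=ids, responses=values,
                          pair_index=pair_index, column_names=columns)


def write_response_matrix(rm: ResponseMatrix, path) -> None:
    """Write a ResponseMatrix back to the CSV dialect read_response_matrix reads."""
    df = pd.DataFrame(rm.responses, columns=rm.column_names)
    df.insert(0, "Participant", rm.participant_ids)
    df.to_csv(path, index=False)


def _patterns_for_row(row: np.ndarray, pair_index) -> PatternCounts:
    counts = dict.fromkeys(PATTERNS, 0)
    for ja, jn in pair_index:
        counts[classify_pair(row[ja], row[jn])] += 1
    return PatternCounts(**counts)


def tabulate_patterns(rm: ResponseMatrix, scope: str = "pooled"):
    """Tabulate the paired response patterns a, b, c, d.

    With ``scope="pooled"`` returns a single :class:`PatternCounts` with
    N = n*k; with ``scope="per_participant"`` returns a dict mapping each
    participant ID to its own counts (each with N = k).
    """
    per = {pid: _patterns_for_row(rm.responses[i], rm.pair_index)
           for i, pid in enumerate(rm.participant_ids)}
    if scope == "per_participant":
        return per
    if scope == "pooled":
        total = PatternCounts(0, 0, 0, 0)
        for pc in per.values():
            total = total + pc
        return total
    raise ValueError(f"unknown scope {scope!r}")


def sdt_counts(rm: ResponseMatrix, scope: str = "pooled"):
    """Hit / miss / FA / CR counts, per participant or pooled."""
    pat = tabulate_patterns(rm, scope)
    if scope == "pooled":
        return SDTCounts.from_patterns(pat)
    return {pid: SDTCounts.from_patterns(pc) for pid, pc in pat.items()}


def answers_A_per_participant(rm: ResponseMatrix) -> np.ndarray:
    """Number of "A" answers per participant, out of m = 2k trials.

    This is the per-participant row sum of the response matrix (hits plus
    false alarms); it is the input for the replication adjustment factor.
    """
    return rm.responses.sum(axis=1).astype(int)
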