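import numpy as np
import pytest

from anota import ResponseMatrix

# Worked example layout: k = 3 pairs, columns sorted by stimulus class
# (three A columns then three Not-A columns, paired positionally).
EXAMPLE_HEADER = ["Participant", "Stim01_A", "Stim03_A", "Stim05_A",
                  "Stim02_NotA", "Stim04_NotA", "Stim06_NotA"]
EXAMPLE_ROWS = [
    ["1", "0", "0", "1", "1", "1", "1"],
    ["2", "0", "1", "0", "0", "0", "1"],
    ["3", "1", "0", "1", "0", "0", "0"],
]


@pytest.fixture
def example_csv(tmp_path):
    path = tmp_path / "responses.csv"
    lines = [",".join(EXAMPLE_HEADER)] + [",".join(r) for r in EXAMPLE_ROWS]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def example_matrix():
    return ResponseMatrix(
        participant_ids=["1", "2", "3"],
        responses=np.array([[0, 0, 1, 1, 1, 1],
                            [0, 1, 0, 0, 0, 1],
                            [1, 0, 1, 0, 0, 0]]),
        pair_index=[(0, 3), (1, 4), (2, 5)],
        column_names=EXAMPLE_HEADER[1:],
    )


@pytest.fixture
def all_correct_matrix():
    """One participant who classifies all k = 6 pairs correctly."""
    return ResponseMatrix(
        participant_ids=["p1"],
        responses=np.concatenate([np.ones(6, dtype=int),
                                  np.zeros(6, dtype=int)])[None, :],
        pair_index=[(j, 6 + j) for j in range(6)],
    )
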