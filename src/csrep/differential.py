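"""Differential chromatin state scoring between two sample groups.

The differential matrix is the elementwise difference of two groups' summary
probability matrices, D12 = R1 - R2: a G x S matrix of signed scores in
[-1, 1].  Score +1 at (bin i, state s) means group 1 is assigned state s
with probability 1 where group 2 never is; -1 the reverse.  Because each
state gets its own signed track, the scores localize *which* state changes
and in which direction.

Per-position statistical baselines operate on the binary "sample is in state
s" indicator at each bin: Fisher's exact test on the 2x2 group-by-indicator
table, and the Mann-Whitney U test on the two groups' indicator vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome import GenomeIndex, SampleGroup, StateScheme
from .summarize import SummaryMatrix

__all__ = [
    "DifferentialMatrix",
    "PositionTestTrack",
    "differential_scores",
    "fisher_position_test",
    "mannwhitney_position_test",
    "benjamini_hochberg",
]


@dataclass
class DifferentialMatrix:
    """Signed per-state differential scores between two groups."""

    group1_id: str
    group2_id: str
    scores: np.ndarray  # G x S in [-1, 1]
    method: str
    index: GenomeIndex
    scheme: StateScheme

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (self.index.n_bins, self.scheme.S):
            raise ValueError("scores must be G x S")


@dataclass
class PositionTestTrack:
    """Per-bin p-values and direction signs for one state's group contrast."""

    state: int
    test: str  # "fisher" | "mannwhitney"
    values: np.ndarray  # two-sided p-values, length G
    direction: np.ndarray  # +1 / -1 / 0, length G


def differential_scores(r1: SummaryMatrix, r2: SummaryMatrix) -> DifferentialMatrix:
    """D12 = R1 - R2 for two summaries of the same genome and scheme.

    Antisymmetric under swapping the groups; entries are bounded by 1 in
    absolute value because each input entry is a probability.
    """
    if r1.index != r2.index:
        raise ValueError("summaries use different genome indexes")
    if r1.scheme != r2.scheme:
        raise ValueError("summaries use different state schemes")
    if r1.method != r2.method:
        raise ValueError(
            f"summaries were produced by different methods "
            f"({r1.method!r} vs {r2.method!r})"
        )
    return DifferentialMatrix(
        group1_id=r1.group_id, group2_id=r2.group_id,
        scores=r1.probs - r2.probs, method=r1.method,
        index=r1.index, scheme=r1.scheme,
    )


def _check_groups(group1: SampleGroup, group2: SampleGroup, state: int) -> None:
    if group1.N < 1 or group2.N < 1:
        raise ValueError("both groups must be non-empty")
    if group1.index != group2.index or group1.scheme != group2.scheme:
        raise ValueError("groups must share GenomeIndex and StateScheme")
    if not 1 <= state <= group1.scheme.S:
        raise ValueError(f"state {state} outside 1..{group1.scheme.S}")


def _in_state_counts(group: SampleGroup, state: int) -> np.ndarray:
    return (group.state_matrix() == state).sum(axis=1)


def fisher_position_test(
    group1: SampleGroup, group2: SampleGroup, state: int
) -> PositionTestTrack:
    """Two-sided Fisher's exact test at every bin.

    Per bin, the 2x2 table crosses group membership with the indicator of a
    sample being in ``state``.  Since only the per-group in-state counts vary,
    p-values are computed once per distinct (count1, count2) pair.
    """
    _check_groups(group1, group2, state)
    c1 = _in_state_counts(group1, state)
    c2 = _in_state_counts(group2, state)
    n1, n2 = group1.N, group2.N
    pairs = c1 * (n2 + 1) + c2
    uniq, inverse = np.unique(pairs, return_inverse=True)
    pu = np.empty(uniq.size)
    for j, key in enumerate(uniq):
        a, b = int(key) // (n2 + 1), int(key) % (n2 + 1)
        pu[j] = stats.fisher_exact(
            [[a, n1 - a], [b, n2 - b]], alternative="two-sided"
        )[1]
    values = np.minimum(pu[inverse], 1.0)
    direction = np.sign(c1 / n1 - c2 / n2).astype(np.int8)
    return PositionTestTrack(state=state, test="fisher", values=values, direction=direction)


def mannwhitney_position_test(
    group1: SampleGroup, group2: SampleGroup, state: int
) -> PositionTestTrack:
    """Two-sided Mann-Whitney U test at every bin on binary indicators.

    Uses the normal approximation with tie correction and continuity
    correction (exact enumeration is degenerate on binary, heavily tied
    data).  Bins where every sample carries the same indicator value are
    complete ties: p = 1, direction 0.
    """
    _check_groups(group1, group2, state)
    c1 = _in_state_counts(group1, state)
    c2 = _in_state_counts(group2, state)
    n1, n2 = group1.N, group2.N
    pairs = c1 * (n2 + 1) + c2
    uniq, inverse = np.unique(pairs, return_inverse=True)
    pu = np.empty(uniq.size)
    for j, key in enumerate(uniq):
        a, b = int(key) // (n2 + 1), int(key) % (n2 + 1)
        if a + b == 0 or a + b == n1 + n2:
            pu[j] = 1.0
            continue
        x = np.concatenate([np.ones(a), np.zeros(n1 - a)])
        y = np.concatenate([np.ones(b), np.zeros(n2 - b)])
        pu[j] = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )[1]
    values = np.minimum(pu[inverse], 1.0)
    direction = np.sign(c1 / n1 - c2 / n2).astype(np.int8)
    return PositionTestTrack(state=state, test="mannwhitney", values=values, direction=direction)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (utility; evaluation ranks raw
    scores and p-values, so no correction is applied by default)."""
    return stats.false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")
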