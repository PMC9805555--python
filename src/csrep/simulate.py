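"""Synthetic segmentation generator with known ground truth.

Real multi-sample chromatin state compendia share a latent "tissue
consensus" annotation that individual samples report with sample-specific
noise.  This module emulates that structure directly: a segmental consensus
state sequence (geometric segment lengths, no two adjacent segments alike),
per-sample bin-wise confusion noise (sample reports state j where the
consensus has state i with probability ``confusion[i, j]``), and, for
two-group comparisons, planted regions where the second group's consensus is
rewritten to a different state.

Everything is deterministic given (config, seed): seeds for the consensus
and each group are spawned from the config seed, so regenerating any piece
reproduces it bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .genome import GenomeIndex, SampleGroup, StateMap, StateScheme

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "default_confusion",
    "confusable_pair_confusion",
    "generate_consensus",
    "generate_group",
    "generate_differential_pair",
    "structured_noise_group",
]

# Default study conditions: a small group (N=3) over a 5-state alphabet on a
# 2000-bin genome with ~10-bin consensus segments and 88% per-bin reporting
# fidelity spread uniformly over the other states.
DEFAULT_S = 5
DEFAULT_G = 2000
DEFAULT_N = 3
DEFAULT_SEGMENT_MEAN = 10.0
DEFAULT_DIAGONAL = 0.88


def default_confusion(S: int, diagonal: float = DEFAULT_DIAGONAL) -> np.ndarray:
    """Row-stochastic confusion with constant diagonal and uniform spill."""
    if not 0 < diagonal <= 1:
        raise ValueError("diagonal must be in (0, 1]")
    off = (1.0 - diagonal) / (S - 1)
    M = np.full((S, S), off)
    np.fill_diagonal(M, diagonal)
    return M


def confusable_pair_confusion(
    S: int,
    pair: tuple[int, int] = (1, 2),
    cross: float = 0.3,
    diagonal: float = DEFAULT_DIAGONAL,
) -> np.ndarray:
    """Structured noise: state ``pair[0]`` is systematically mis-reported as
    ``pair[1]`` with probability ``cross`` (1-based states), on top of the
    uniform baseline confusion."""
    a, b = pair
    M = default_confusion(S, diagonal)
    M[a - 1, b - 1] += cross
    M[a - 1, a - 1] -= cross
    if M[a - 1, a - 1] < 0:
        raise ValueError("cross-reporting exceeds the diagonal mass")
    return M


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic group (or pair of groups)."""

    S: int = DEFAULT_S
    G: int = DEFAULT_G
    N: int = DEFAULT_N
    segment_length_mean: float = DEFAULT_SEGMENT_MEAN
    confusion: np.ndarray | None = None  # default: default_confusion(S)
    planted_regions: tuple[tuple[int, int, int, int], ...] = ()  # (start, end, from, to)
    seed: int = 0
    bin_size: int = 200

    def __post_init__(self) -> None:
        if self.S < 2:
            raise ValueError("need at least 2 states")
        if self.G < 1:
            raise ValueError("need at least 1 bin")
        if self.N < 1:
            raise ValueError("need at least 1 sample")
        if self.segment_length_mean < 1:
            raise ValueError("segment_length_mean must be >= 1 bin")
        M = self.confusion if self.confusion is not None else default_confusion(self.S)
        M = np.asarray(M, dtype=float)
        if M.shape != (self.S, self.S):
            raise ValueError("confusion must be S x S")
        if np.any(M < 0) or not np.allclose(M.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("confusion rows must be non-negative and sum to 1")
        object.__setattr__(self, "confusion", M)
        spans = sorted((r[0], r[1]) for r in self.planted_regions)
        for (start, end, s_from, s_to) in self.planted_regions:
            if not (0 <= start < end <= self.G):
                raise ValueError(f"planted region ({start},{end}) outside [0, G)")
            for s in (s_from, s_to):
                if not 1 <= s <= self.S:
                    raise ValueError("planted states must lie in 1..S")
        for (a, b), (c, d) in zip(spans, spans[1:]):
            if c < b:
                raise ValueError("planted regions must not overlap")

    def genome_index(self) -> GenomeIndex:
        return GenomeIndex(chromosomes=(("chr1", self.G * self.bin_size),),
                           bin_size=self.bin_size)

    def state_scheme(self) -> StateScheme:
        return StateScheme.from_n_states(self.S)


@dataclass
class SyntheticTruth:
    """Ground truth for a planted two-group comparison."""

    config: GeneratorConfig
    consensus1: np.ndarray
    consensus2: np.ndarray
    planted_mask: np.ndarray  # 1 where the two consensuses were rewritten
    group1: SampleGroup
    group2: SampleGroup
    planted_mismatch: bool = False  # a planted state_from disagreed with consensus1


def _spawn_rngs(seed, n: int) -> list[np.random.Generator]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def generate_consensus(config: GeneratorConfig, seed: int | None = None) -> np.ndarray:
    """Segmental consensus: geometric segment lengths with the configured
    mean; each segment's state drawn uniformly among states different from
    the previous segment's."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    G, S = config.G, config.S
    p = 1.0 / config.segment_length_mean
    out = np.empty(G, dtype=np.int32)
    pos = 0
    prev = 0  # no exclusion for the first segment
    while pos < G:
        length = rng.geometric(p)
        choices = [s for s in range(1, S + 1) if s != prev]
        state = int(rng.choice(choices))
        out[pos: pos + length] = state
        pos += length
        prev = state
    return out


def generate_group(
    consensus: np.ndarray,
    config: GeneratorConfig,
    group_seed: "int | np.random.SeedSequence",
    group_id: str = "group",
    confusions: list[np.ndarray] | None = None,
) -> SampleGroup:
    """Draw N sample maps bin-wise independently from the confusion rows of
    the consensus states.  ``confusions`` optionally gives one matrix per
    sample (structured, sample-specific noise); default: the config matrix
    for every sample."""
    consensus = np.asarray(consensus, dtype=np.int32)
    if consensus.shape != (config.G,):
        raise ValueError("consensus length must equal G")
    if confusions is None:
        confusions = [config.confusion] * config.N
    if len(confusions) != config.N:
        raise ValueError("need one confusion matrix per sample")
    index = config.genome_index()
    scheme = config.state_scheme()
    rngs = _spawn_rngs(group_seed, config.N)
    members = []
    for n, (rng, M) in enumerate(zip(rngs, confusions), 1):
        M = np.asarray(M, dtype=float)
        if M.shape != (config.S, config.S) or np.any(M < 0) or \
                not np.allclose(M.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError(f"invalid confusion matrix for sample {n}")
        states = np.empty(config.G, dtype=np.int32)
        for s in range(1, config.S + 1):
            where = np.flatnonzero(consensus == s)
            if where.size:
                states[where] = rng.choice(
                    np.arange(1, config.S + 1), size=where.size, p=M[s - 1]
                )
        members.append(StateMap(sample_id=f"{group_id}_s{n}", states=states,
                                index=index, scheme=scheme))
    return SampleGroup(group_id=group_id, members=members)


def generate_differential_pair(config: GeneratorConfig) -> SyntheticTruth:
    """Two groups sharing a consensus except on planted regions.

    Group 2's consensus is group 1's with each planted region rewritten from
    ``state_from`` to ``state_to``; both groups' samples are then drawn
    independently.  If a planted ``state_from`` disagrees with the consensus
    at some bins, the rewrite still happens and the truth is flagged.
    """
    ss = np.random.SeedSequence(config.seed).spawn(3)
    consensus1 = generate_consensus(config, seed=ss[0])
    consensus2 = consensus1.copy()
    mask = np.zeros(config.G, dtype=np.int8)
    mismatch = False
    for (start, end, s_from, s_to) in config.planted_regions:
        if np.any(consensus1[start:end] != s_from):
            mismatch = True
            warnings.warn(
                f"planted region ({start},{end}): consensus disagrees with "
                f"state_from={s_from} at some bins; rewriting anyway",
                RuntimeWarning,
            )
        consensus2[start:end] = s_to
        mask[start:end] = consensus2[start:end] != consensus1[start:end]
    g1 = generate_group(consensus1, config, group_seed=ss[1], group_id="group1")
    g2 = generate_group(consensus2, config, group_seed=ss[2], group_id="group2")
    return SyntheticTruth(config=config, consensus1=consensus1, consensus2=consensus2,
                          planted_mask=mask, group1=g1, group2=g2,
                          planted_mismatch=mismatch)


def structured_noise_group(
    config: GeneratorConfig,
    pair: tuple[int, int] = (1, 2),
    cross: float = 0.3,
    n_confused: int = 1,
    group_id: str = "structured",
) -> tuple[np.ndarray, SampleGroup]:
    """The documented structured-noise scenario: a consensus group in which a
    minority of samples (the last ``n_confused`` members) systematically
    mis-report one state as another (default: state 1 reported as state 2
    with probability 0.3), on top of the baseline uniform confusion."""
    if not 0 < n_confused < config.N:
        raise ValueError("n_confused must leave a majority of clean samples")
    ss = np.random.SeedSequence(config.seed).spawn(2)
    consensus = generate_consensus(config, seed=ss[0])
    clean = config.confusion
    noisy = confusable_pair_confusion(config.S, pair=pair, cross=cross)
    confusions = [clean] * (config.N - n_confused) + [noisy] * n_confused
    group = generate_group(consensus, config, group_seed=ss[1],
                           group_id=group_id, confusions=confusions)
    return consensus, group
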