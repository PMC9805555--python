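import numpy as np
import pytest

from csrep import GenomeIndex, SampleGroup, StateMap, StateScheme


@pytest.fixture
def toy_index():
    """Single 1000-bp chromosome at 200-bp bins: 5 bins."""
    return GenomeIndex(chromosomes=(("chrT", 1000),), bin_size=200)


@pytest.fixture
def scheme2():
    return StateScheme.from_n_states(2)


@pytest.fixture
def scheme5():
    return StateScheme.from_n_states(5)


@pytest.fixture
def make_group():
    """Factory for random small groups: make_group(N, S, G, seed)."""

    def _make(N=3, S=4, G=50, seed=0, group_id="g"):
        rng = np.random.default_rng(seed)
        index = GenomeIndex(chromosomes=(("chr1", G * 200),), bin_size=200)
        scheme = StateScheme.from_n_states(S)
        members = [
            StateMap(sample_id=f"s{n}", states=rng.integers(1, S + 1, size=G),
                     index=index, scheme=scheme)
            for n in range(N)
        ]
        return SampleGroup(group_id=group_id, members=members)

    return _make
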