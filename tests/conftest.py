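import numpy as np
import pytest

from tipchron.phylo import Alignment, SubstModel
from tipchron.simulate import simulate_coalescent_tree, simulate_sequences
from tipchron.tree import TimeTree


@pytest.fixture
def freqs():
    return np.array([0.32, 0.26, 0.13, 0.29])


@pytest.fixture
def model(freqs):
    return SubstModel(kappa=8.0, base_freqs=freqs, alpha=0.5, rate=3e-8)


@pytest.fixture
def two_tip_tree():
    # cherry: two contemporaneous tips coalescing 12,345 years back
    return TimeTree(
        ["a", "b"],
        parent=[2, 2, -1],
        children=[[-1, -1], [-1, -1], [0, 1]],
        ages=[0.0, 0.0, 12_345.0],
    )


@pytest.fixture
def serial_tree():
    """10 serially sampled tips, fixed genealogy."""
    rng = np.random.default_rng(42)
    ages = np.sort(rng.uniform(0, 3e5, 10))
    ages[0] = 0.0
    return simulate_coalescent_tree(ages, 1e5, seed=43)


@pytest.fixture
def small_alignment(serial_tree, freqs):
    return simulate_sequences(
        serial_tree, 3e-8, 8.0, 0.5, freqs, seq_length=2_000, seed=44
    )


@pytest.fixture
def four_taxon_tree():
    return simulate_coalescent_tree([0.0, 0.0, 5e4, 1.2e5], 1e5, seed=7)


def make_alignment(ids, rows):
    return Alignment(list(ids), list(rows))
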