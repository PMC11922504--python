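import numpy as np
import pytest

from bovid_admix.fstats import BlockPartition, PopulationSpec
from bovid_admix.simulate import simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 5k-site dataset with one alpha = 0.4 pseudohaploid target."""
    matrix, blocks, truth, freqs = simulate_dataset(
        [("target", 0.4, None)], n_sites=5000, seed=11)
    return matrix, blocks, truth, freqs


@pytest.fixture(scope="session")
def qpadm_dataset():
    """A 20k-site dataset with one alpha = 0.25 target for model fitting."""
    matrix, blocks, truth, freqs = simulate_dataset(
        [("target", 0.25, None)], n_sites=20000, seed=23)
    return matrix, blocks, truth, freqs


def pop(matrix, group):
    return PopulationSpec(group, matrix.members_of(group))


@pytest.fixture
def pops():
    return pop
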