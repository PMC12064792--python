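import numpy as np
import pytest

from trapexpert.grouping import GroupAssignment
from trapexpert.simulate import benchmark_species, planted_group_confusion


@pytest.fixture(scope="session")
def benchmark():
    """Species codes, the four appearance groups, and abundance weights of
    the published 24-species benchmark."""
    species, groups, weights = benchmark_species()
    return species, groups, weights


@pytest.fixture(scope="session")
def small_groups():
    """A small planted regime: two appearance groups of two species each."""
    return [["cer", "dam"], ["lep", "ory"]]


@pytest.fixture(scope="session")
def small_profiles(small_groups):
    return planted_group_confusion(small_groups, within_rate=0.3,
                                   across_rate=0.01, miss_rate=0.05)


@pytest.fixture(scope="session")
def small_assignment(small_groups):
    return GroupAssignment.from_groups(small_groups)


def random_distance_matrix(rng: np.random.Generator, n: int,
                           discretize: bool = False) -> np.ndarray:
    """Random symmetric zero-diagonal distance matrix; ``discretize`` rounds
    to one decimal so that exact linkage ties occur."""
    d = rng.random((n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    if discretize:
        d = np.round(d, 1)
    return d
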