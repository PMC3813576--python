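import numpy as np
import pytest

from pollindep.io import CensusRecord, SeedSetRecord, load_study_table
from pollindep.network import BipartiteNetwork


@pytest.fixture(scope="session")
def sb_table():
    return load_study_table("SB")


@pytest.fixture(scope="session")
def pm_table():
    return load_study_table("PM")


@pytest.fixture
def small_census():
    """2 plants x 3 pollinators with a repeated (A, x) pair."""
    return [
        CensusRecord("A", "x", 6, 2, 3),
        CensusRecord("A", "x", 0, 1, 3),
        CensusRecord("A", "y", 2, 1, 4),
        CensusRecord("B", "y", 3, 3, 1),
        CensusRecord("B", "z", 1, 1, 5),
    ]


@pytest.fixture
def small_seedset():
    return [
        SeedSetRecord("A", "OP", 10, 30),
        SeedSetRecord("A", "OP", 5, 0),
        SeedSetRecord("A", "PE", 10, 5),
        SeedSetRecord("B", "OP", 8, 16),
        SeedSetRecord("B", "PE", 8, 16),
    ]


def random_network(rng: np.random.Generator, p: int, a: int, density: float = 0.4):
    """Small random weighted bipartite net where every plant has >= 1 link."""
    weights = rng.uniform(0.1, 2.0, size=(p, a)) * (rng.uniform(size=(p, a)) < density)
    for i in range(p):
        if not weights[i].any():
            weights[i, rng.integers(a)] = rng.uniform(0.1, 2.0)
    return BipartiteNetwork(
        [f"P{i}" for i in range(p)], [f"I{j}" for j in range(a)], weights
    )
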