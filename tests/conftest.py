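import numpy as np
import pytest

from cryptomotu.distances import k2p_matrix
from cryptomotu.synthetic_data import SimulationConfig, simulate


@pytest.fixture(scope="session")
def sim5():
    """Small five-lineage synthetic dataset with ground truth."""
    return simulate(SimulationConfig(n_lineages=5, n_sites=25, seed=11))


@pytest.fixture(scope="session")
def sim5_matrix(sim5):
    return k2p_matrix(sim5.haplotypes, min_overlap=300)


@pytest.fixture(scope="session")
def sim12():
    """Default study conditions: twelve deeply divergent lineages."""
    return simulate(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def sim12_matrix(sim12):
    return k2p_matrix(sim12.haplotypes, min_overlap=300)


def random_distance_matrix(rng: np.random.Generator, n: int):
    """Symmetric random matrix with zero diagonal, occasional NaNs."""
    d = rng.uniform(0, 0.3, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    mask = rng.random((n, n)) < 0.05
    mask = np.triu(mask, k=1)
    d[mask] = np.nan
    d[mask.T] = np.nan
    return d
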