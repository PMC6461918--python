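import numpy as np
import pytest

from moob.core import BreedingValues, GenotypeMatrix, compute_relationship
from moob.sim import SimulationConfig, make_founders


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genotypes():
    """Hand-sized 3 x 4 dosage matrix used for element-by-element oracles."""
    D = np.array(
        [
            [0, 1, 2, 1],
            [2, 0, 1, 1],
            [1, 2, 0, 0],
        ]
    )
    return GenotypeMatrix.from_dosages(D)


def small_config(**overrides) -> SimulationConfig:
    """A scaled-down simulation configuration for fast unit tests."""
    kw = dict(
        pop_size=30,
        n_markers_per_chrom=60,
        n_chrom=3,
        n_qtl_per_chrom=12,
        n_opposite_sign=6,
        burnin_random_mating=20,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


@pytest.fixture(scope="session")
def small_founders():
    return make_founders(small_config(), seed=7)


@pytest.fixture(scope="session")
def frontier_instance():
    """A small random candidate set: breeding values + relationship matrix."""
    rng = np.random.default_rng(42)
    D = rng.integers(0, 3, size=(8, 40))
    G = GenotypeMatrix.from_dosages(D)
    A = compute_relationship(G)
    bv = BreedingValues(rng.normal(size=(8, 2)), ["t1", "t2"])
    return bv, A
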