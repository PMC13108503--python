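import numpy as np
import pytest

from netseg import Parcellation, WeightedAdjacency, default_parcellation


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def parc3():
    """9 ROIs in three networks of three."""
    names = tuple(f"r{i}" for i in range(9))
    nets = ("A",) * 3 + ("B",) * 3 + ("C",) * 3
    return Parcellation(names, nets)


@pytest.fixture
def parc2():
    """6 ROIs in two networks of three."""
    names = tuple(f"r{i}" for i in range(6))
    return Parcellation(names, ("A",) * 3 + ("B",) * 3)


@pytest.fixture
def parc200():
    return default_parcellation(200, 7)


def random_weighted(n: int, rng) -> WeightedAdjacency:
    """Random symmetric nonnegative weights with zero diagonal."""
    w = rng.uniform(0, 1, size=(n, n))
    w = np.triu(w, 1)
    w = w + w.T
    return WeightedAdjacency(w)


@pytest.fixture
def random_weighted_factory(rng):
    return lambda n: random_weighted(n, rng)
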