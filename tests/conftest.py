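import numpy as np
import pytest

from netora.network import GeneNetwork
from netora.weighting import GeneSet, GeneSetCollection


@pytest.fixture
def triangle():
    return GeneNetwork(["a", "b", "c"], [("a", "b", 1), ("a", "c", 1), ("b", "c", 1)])


@pytest.fixture
def path3():
    return GeneNetwork(["a", "b", "c"], [("a", "b", 1), ("b", "c", 1)])


@pytest.fixture
def n4():
    """Toy network: a-b, a-c, b-c, c-d, all unit weights; bgNE = 5/6."""
    return GeneNetwork(
        ["a", "b", "c", "d"],
        [("a", "b", 1), ("a", "c", 1), ("b", "c", 1), ("c", "d", 1)],
    )


@pytest.fixture
def set_ab():
    return GeneSet("S", frozenset(["a", "b"]))


def random_network(rng: np.random.Generator, m: int, p: float = 0.3) -> GeneNetwork:
    """Erdos-Renyi helper used by oracle and property tests."""
    genes = [f"g{i}" for i in range(m)]
    iu, ju = np.triu_indices(m, k=1)
    present = rng.random(len(iu)) < p
    weights = rng.uniform(0.1, 1.0, size=len(iu))
    edges = [
        (genes[i], genes[j], float(w))
        for i, j, w, keep in zip(iu, ju, weights, present)
        if keep
    ]
    return GeneNetwork(genes, edges)


def random_geneset(rng: np.random.Generator, net: GeneNetwork, size: int) -> GeneSet:
    members = rng.choice(net.m, size=size, replace=False)
    return GeneSet("rset", frozenset(net.genes[i] for i in members))
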