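import numpy as np
import pytest

from netprop.interactome import Interactome, normalize
from netprop.synthetic import SyntheticSpec, generate


@pytest.fixture
def triangle():
    return Interactome.from_edges(
        [("a", "b", 900), ("b", "c", 800), ("a", "c", 750)]
    )


@pytest.fixture
def path_graph():
    return Interactome.from_edges([("a", "b", 900), ("b", "c", 900)])


@pytest.fixture
def star_graph():
    """K_{1,3}: hub h with leaves x, y, z."""
    return Interactome.from_edges(
        [("h", "x", 900), ("h", "y", 900), ("h", "z", 900)]
    )


def random_network(n: int, p: float, seed: int, isolated: int = 0) -> Interactome:
    """Erdos–Renyi test network; optionally append isolated genes."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n + isolated)]
    edges = [
        (genes[i], genes[j], 900)
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return Interactome.from_edges(edges, extra_nodes=genes)


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic dataset at the documented default spec, fixed seed."""
    spec = SyntheticSpec(seed=3)
    net, layers, truth = generate(spec)
    return net, layers, truth


@pytest.fixture(scope="session")
def default_scored(default_dataset):
    """Default dataset taken through diffusion scoring (no permutations)."""
    from netprop.layers import build_matrix
    from netprop.diffusion import score_genes

    net, layers, truth = default_dataset
    X0 = build_matrix(layers, net)
    result = score_genes(net, normalize(net), X0)
    return net, layers, truth, X0, result
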