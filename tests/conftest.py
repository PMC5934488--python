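import numpy as np
import pytest

from restnet.atlas import build_roi_atlas


@pytest.fixture(scope="session")
def atlas():
    return build_roi_atlas()


def random_weighted_graph(rng: np.random.Generator, n: int,
                          density: float = 1.0) -> np.ndarray:
    """Random symmetric weighted adjacency; connected when density = 1."""
    W = np.triu(rng.uniform(0.05, 1.0, (n, n)), k=1)
    if density < 1.0:
        keep = np.triu(rng.random((n, n)) < density, k=1)
        # keep a random spanning path so the graph stays connected
        order = rng.permutation(n)
        for a, b in zip(order[:-1], order[1:]):
            i, j = min(a, b), max(a, b)
            keep[i, j] = True
        W = np.where(keep, W, 0.0)
    return W + W.T


def random_tree_edges(rng: np.random.Generator, n: int):
    """Uniform-ish random labelled tree via random attachment."""
    edges = []
    nodes = rng.permutation(n)
    for idx in range(1, n):
        parent = nodes[rng.integers(0, idx)]
        child = nodes[idx]
        edges.append((min(parent, child), max(parent, child)))
    return tuple(sorted((int(a), int(b)) for a, b in edges))
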