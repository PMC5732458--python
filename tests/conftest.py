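import numpy as np
import pytest

from coreg.netio import DirectedNetwork


@pytest.fixture
def toy_net() -> DirectedNetwork:
    """A and B share out-neighbors {y, z}; A also -> x, B also -> w."""
    return DirectedNetwork.from_edges(
        [("A", "x"), ("A", "y"), ("A", "z"), ("B", "y"), ("B", "z"), ("B", "w")]
    )


@pytest.fixture
def two_block_net() -> DirectedNetwork:
    """Two planted regulator groups with identical within-group targets."""
    edges = []
    for r in ("a1", "a2", "a3"):
        edges += [(r, t) for t in ("p", "q", "s")]
    for r in ("b1", "b2", "b3"):
        edges += [(r, t) for t in ("u", "v", "w")]
    return DirectedNetwork.from_edges(edges)


def random_digraph(rng: np.random.Generator, max_nodes: int = 50) -> DirectedNetwork:
    """Random clean Erdos-Renyi digraph with at least one edge."""
    while True:
        n = int(rng.integers(3, max_nodes + 1))
        p = float(rng.uniform(0.05, 0.4))
        mask = rng.random((n, n)) < p
        np.fill_diagonal(mask, False)
        rows, cols = np.nonzero(mask)
        if len(rows):
            break
    names = [f"g{i}" for i in range(n)]
    return DirectedNetwork.from_edges([(names[i], names[j]) for i, j in zip(rows, cols)])


def brute_force_similarity(net: DirectedNetwork, index: str, direction: str):
    """Independent oracle: explicit set arithmetic over adjacency lists."""
    import math

    neigh = {
        g: (net.in_neighbors(g) if direction == "in" else net.out_neighbors(g))
        for g in net.nodes
    }
    degree = {g: len(net.in_neighbors(g)) + len(net.out_neighbors(g)) for g in net.nodes}
    n = len(net.nodes)
    out = np.zeros((n, n))
    for i, gi in enumerate(net.nodes):
        for j, gj in enumerate(net.nodes):
            if i == j:
                continue
            common = neigh[gi] & neigh[gj]
            if index == "jaccard":
                union = neigh[gi] | neigh[gj]
                out[i, j] = len(common) / len(union) if union else 0.0
            elif index == "geometric":
                denom = len(neigh[gi]) * len(neigh[gj])
                out[i, j] = len(common) ** 2 / denom if denom else 0.0
            elif index == "invlogweighted":
                out[i, j] = sum(1.0 / math.log(degree[c]) for c in common)
            else:
                raise ValueError(index)
    return out
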