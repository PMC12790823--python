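import numpy as np
import pytest

from stgap import (
    FixtureSpec,
    SpatialGraph,
    generate_fixture,
    generate_partition_testgraphs,
)


@pytest.fixture(scope="session")
def testgraphs():
    """Small named graphs (<= 8 nodes) used as exhaustive partitioner oracles."""
    return generate_partition_testgraphs(n_max=8, seed=0)


@pytest.fixture(scope="session")
def small_fixture():
    """A reduced planted-domain section (600 spots) for fast training tests."""
    spec = FixtureSpec(grid=(30, 20), n_domains=3, n_genes=60, seed=1)
    ds, labels = generate_fixture(spec)
    return spec, ds, labels


@pytest.fixture
def path4():
    return SpatialGraph.from_edges(4, [(0, 1), (1, 2), (2, 3)])


@pytest.fixture
def cycle4():
    return SpatialGraph.from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])


def brute_force_edge_cut(g: SpatialGraph, labels) -> int:
    """O(n^2) oracle: count unordered non-self adjacent pairs with differing labels."""
    labels = np.asarray(labels)
    A = g.adjacency.toarray()
    n = g.n_nodes
    return sum(
        1
        for i in range(n)
        for j in range(i + 1, n)
        if A[i, j] and labels[i] != labels[j]
    )


def exhaustive_min_balanced_cut(g: SpatialGraph) -> int:
    """Minimum 2-cut over all bipartitions with part weights within one node."""
    n = g.n_nodes
    best = None
    for mask in range(1, 2 ** (n - 1)):  # fix node 0 in part 0
        labels = np.array([(mask >> i) & 1 for i in range(n)])
        w0 = int(g.node_weight[labels == 0].sum())
        w1 = int(g.node_weight[labels == 1].sum())
        if abs(w0 - w1) > g.node_weight.max():
            continue
        cut = brute_force_edge_cut(g, labels)
        best = cut if best is None else min(best, cut)
    return best
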