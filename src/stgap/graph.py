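"""Spatial neighbor graphs.

Spots are connected when their Euclidean distance is strictly below a radius
``r``; every node carries a self-loop so that graph-attention aggregation
always sees the node itself.  The graph is stored as a symmetric boolean CSR
adjacency matrix plus an integer node-weight vector (all ones for an original
section; coarsening accumulates weights into supernodes).
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

__all__ = [
    "SpatialGraph",
    "build_radius_graph",
    "mean_neighbor_count",
    "adaptive_radius",
    "DEFAULT_NEIGHBOR_BAND",
]

#: Mean non-self neighbor band within which clustering quality is stable
#: across platforms/resolutions.
DEFAULT_NEIGHBOR_BAND = (10.0, 30.0)


class SpatialGraph:
    """Undirected unweighted graph with mandatory self-loops.

    Parameters
    ----------
    adjacency
        Square sparse boolean matrix.  It is symmetrized, and self-loops are
        added on construction, so callers may pass either half of the edge set.
    node_weight
        Positive integer weight per node (number of original spots a node
        represents).  Defaults to all ones.
    """

    def __init__(self, adjacency: sp.spmatrix, node_weight: np.ndarray | None = None):
        A = sp.csr_matrix(adjacency, dtype=np.uint8)
        if A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        A = (A + A.T).astype(bool).astype(np.uint8)
        A.setdiag(1)
        A.eliminate_zeros()
        A.sort_indices()
        self.adjacency: sp.csr_matrix = A
        if node_weight is None:
            node_weight = np.ones(A.shape[0], dtype=np.int64)
        self.node_weight = np.asarray(node_weight, dtype=np.int64)
        if self.node_weight.shape != (A.shape[0],) or (self.node_weight <= 0).any():
            raise ValueError("node_weight must be positive, one entry per node")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def indptr(self) -> np.ndarray:
        return self.adjacency.indptr

    @property
    def indices(self) -> np.ndarray:
        return self.adjacency.indices

    @property
    def n_directed_edges(self) -> int:
        """Number of directed (i, j) entries including self-loops."""
        return self.adjacency.nnz

    def neighbors(self, i: int) -> np.ndarray:
        """Neighbor indices of node ``i`` (self included)."""
        return self.indices[self.indptr[i]: self.indptr[i + 1]]

    def degree(self, include_self: bool = False) -> np.ndarray:
        """Per-node neighbor count; self-loops excluded unless requested."""
        deg = np.diff(self.indptr)
        return deg if include_self else deg - 1

    def edge_set(self) -> set[tuple[int, int]]:
        """Unordered non-self edge pairs as ``(min, max)`` tuples."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return set(zip(coo.row.tolist(), coo.col.tolist()))

    def total_weight(self) -> int:
        return int(self.node_weight.sum())

    # -- construction helpers ----------------------------------------------
    @classmethod
    def from_edges(cls, n_nodes: int, edges, node_weight=None) -> "SpatialGraph":
        """Build from an iterable of (i, j) pairs; self-loops added for all nodes."""
        edges = list(edges)
        if edges:
            r = np.array([e[0] for e in edges])
            c = np.array([e[1] for e in edges])
            data = np.ones(len(edges), dtype=np.uint8)
            A = sp.coo_matrix((data, (r, c)), shape=(n_nodes, n_nodes))
        else:
            A = sp.coo_matrix((n_nodes, n_nodes), dtype=np.uint8)
        return cls(A, node_weight)

    def subgraph(self, nodes: np.ndarray) -> "SpatialGraph":
        """Induced subgraph on ``nodes`` (order preserved); keeps node weights."""
        nodes = np.asarray(nodes)
        A = self.adjacency[nodes][:, nodes]
        return SpatialGraph(A, self.node_weight[nodes])

    def validate(self) -> None:
        """Raise if symmetry or self-loop invariants are violated."""
        A = self.adjacency
        if (A != A.T).nnz != 0:
            raise AssertionError("adjacency not symmetric")
        if not (A.diagonal() == 1).all():
            raise AssertionError("missing self-loop")

    # -- plain-text IO ------------------------------------------------------
    def to_edgelist(self, path) -> None:
        """Write non-self edges as two 0-based integer columns, one edge per line."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        with open(path, "w") as fh:
            fh.write(f"# n_nodes {self.n_nodes}\n")
            for i, j in zip(coo.row, coo.col):
                fh.write(f"{i} {j}\n")

    @classmethod
    def from_edgelist(cls, path) -> "SpatialGraph":
        edges = []
        n = None
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    n = int(line.split()[-1])
                elif line:
                    i, j = line.split()
                    edges.append((int(i), int(j)))
        if n is None:
            n = max((max(e) for e in edges), default=-1) + 1
        return cls.from_edges(n, edges)

    def __repr__(self) -> str:  # pragma: no cover
        m = (self.n_directed_edges - self.n_nodes) // 2
        return f"SpatialGraph(n_nodes={self.n_nodes}, n_edges={m})"


def build_radius_graph(coords: np.ndarray, r: float) -> SpatialGraph:
    """Connect spots at Euclidean distance strictly below ``r``.

    A k-d tree supplies candidate pairs, so all-pairs distances are never
    materialized.  Ties at exactly ``r`` are excluded; duplicate coordinates
    (distance 0) are connected.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array")
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates")
    if r <= 0:
        raise ValueError("radius must be positive")
    n = coords.shape[0]
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[d < r]  # query_pairs is <= r; the threshold is strict
    A = sp.coo_matrix(
        (np.ones(len(pairs), dtype=np.uint8), (pairs[:, 0], pairs[:, 1]))
        if len(pairs)
        else ([], ([], [])),
        shape=(n, n),
        dtype=np.uint8,
    )
    return SpatialGraph(A)


def mean_neighbor_count(g: SpatialGraph, include_self: bool = False) -> float:
    """Arithmetic mean of per-node neighborhood sizes."""
    return float(g.degree(include_self=include_self).mean())


def _mean_count_at(tree: cKDTree, n: int, r: float) -> float:
    """Mean non-self neighbor count for strict threshold ``< r``, via pair counting."""
    if r <= 0:
        return 0.0
    # count_neighbors uses <= r; nextafter(r, 0) turns it into a strict < r.
    total = tree.count_neighbors(tree, np.nextafter(r, 0))
    return (total - n) / n


def adaptive_radius(
    coords: np.ndarray,
    target_band: tuple[float, float] = DEFAULT_NEIGHBOR_BAND,
    max_iter: int = 80,
) -> float:
    """Choose ``r`` so the mean non-self neighbor count falls in ``target_band``.

    The mean count is a nondecreasing step function of ``r``, so a bisection
    aimed at the band midpoint converges deterministically.  The lower bracket
    is the minimum nearest-neighbor distance; the upper bracket grows
    geometrically from an upper quantile of nearest-neighbor distances until
    the midpoint count is bracketed (capped at the bounding-box diagonal).
    When no radius can reach the band (small sections), the radius that
    maximizes the count is returned with a warning.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least two spots")
    lo_band, hi_band = target_band
    if not lo_band < hi_band:
        raise ValueError("target_band must be increasing")
    mid = 0.5 * (lo_band + hi_band)

    tree = cKDTree(coords)
    nn = tree.query(coords, k=2)[0][:, 1]  # nearest non-self distance
    diag = float(np.linalg.norm(coords.max(axis=0) - coords.min(axis=0)))
    r_all = np.nextafter(diag, np.inf) * (1 + 1e-9) + 1e-300  # complete graph

    max_count = _mean_count_at(tree, n, r_all)
    if max_count < lo_band:
        warnings.warn(
            f"target neighbor band {target_band} unreachable with n={n}; "
            f"returning radius giving the maximum mean count {max_count:.2f}"
        )
        return r_all

    lo = max(float(nn.min()), 1e-12)
    hi = max(float(np.quantile(nn, 0.9)), lo * 2)
    while _mean_count_at(tree, n, hi) < mid and hi < diag:
        hi = min(hi * 2.0, r_all)
    best_in_band = None
    for _ in range(max_iter):
        r = 0.5 * (lo + hi)
        c = _mean_count_at(tree, n, r)
        if lo_band <= c <= hi_band:
            best_in_band = r
        if c < mid:
            lo = r
        else:
            hi = r
    if best_in_band is not None:
        return best_in_band
    # step function jumped over the band (tied lattice distances): pick the
    # bracket end whose count is closest to the midpoint, warn.
    c_lo, c_hi = _mean_count_at(tree, n, lo), _mean_count_at(tree, n, hi)
    r = lo if abs(c_lo - mid) <= abs(c_hi - mid) else hi
    warnings.warn(
        f"no radius lands inside neighbor band {target_band}; "
        f"returning closest achievable mean count"
    )
    return r
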