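"""Synthetic tissue sections with planted spatial domains.

The generator emulates the geometry the method targets: capture spots on a
jittered 2-D lattice, partitioned into K spatially contiguous domains
(horizontal bands, layered-cortex-like, or Voronoi cells), each domain with a
private set of marker genes.  Counts are Poisson — marker genes at
``marker_rate`` inside their domain, everything else at ``background_rate`` —
so the normalization/HVG path downstream is exercised on realistic count
noise.  A companion generator enumerates small named graphs (paths, cycles,
stars, grids, two-blob, random geometric) used as exhaustive oracles for the
partitioner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import SpatialDataset
from .graph import SpatialGraph, build_radius_graph

__all__ = ["FixtureSpec", "generate_fixture", "generate_partition_testgraphs"]


@dataclass
class FixtureSpec:
    """Parameters of a planted-domain section.

    Defaults give a 50x40 grid (2000 spots), 4 horizontal bands, 200 genes
    with 10 markers per domain, marker mean 5 counts vs background 0.2 —
    separable but noisy, sized so the full pipeline runs in minutes on 1 CPU.
    """

    grid: tuple[int, int] = (50, 40)  # (rows, cols), unit spacing
    jitter: float = 0.1  # uniform coordinate noise, fraction of spacing
    n_domains: int = 4
    layout: str = "bands"  # "bands" | "voronoi"
    n_genes: int = 200
    markers_per_domain: int = 10
    marker_rate: float = 5.0
    background_rate: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_domains * self.markers_per_domain > self.n_genes:
            raise ValueError("K * markers_per_domain must not exceed n_genes")
        if not self.marker_rate > self.background_rate:
            raise ValueError("marker_rate must exceed background_rate")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        if self.layout not in ("bands", "voronoi"):
            raise ValueError(f"unknown layout {self.layout!r}")


def generate_fixture(spec: FixtureSpec) -> tuple[SpatialDataset, np.ndarray]:
    """Generate a section; returns the dataset (raw counts) and true domain labels."""
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.grid
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()
    n = rows * cols
    coords = np.column_stack([cc, rr]).astype(float)
    coords += rng.uniform(-0.5, 0.5, size=coords.shape) * spec.jitter

    K = spec.n_domains
    if spec.layout == "bands":
        # rows sliced into K contiguous horizontal bands (as equal as possible)
        edges = np.round(np.linspace(0, rows, K + 1)).astype(int)
        labels = np.searchsorted(edges[1:], rr, side="right")
    else:  # voronoi
        centers = rng.uniform([0, 0], [cols - 1, rows - 1], size=(K, 2))
        d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        labels = d2.argmin(axis=1)
    labels = labels.astype(np.int64)

    rates = np.full((n, spec.n_genes), spec.background_rate)
    for k in range(K):
        g0 = k * spec.markers_per_domain
        rates[labels == k, g0: g0 + spec.markers_per_domain] = spec.marker_rate
    X = rng.poisson(rates).astype(float)

    ds = SpatialDataset(
        expression=X,
        coords=coords,
        spot_ids=np.array([f"spot_{i}" for i in range(n)], dtype=object),
        gene_ids=np.array([f"gene_{j}" for j in range(spec.n_genes)], dtype=object),
    )
    return ds, labels


def marker_classifier_accuracy(ds: SpatialDataset, labels: np.ndarray, spec: FixtureSpec) -> float:
    """Accuracy of the naive rule: assign each spot to the domain whose marker
    block has the highest mean count.  A fixture sanity bound — if this is
    high, downstream clustering failures are the method's, not the fixture's."""
    X = ds.dense()
    K = spec.n_domains
    m = spec.markers_per_domain
    scores = np.stack(
        [X[:, k * m: (k + 1) * m].mean(axis=1) for k in range(K)], axis=1
    )
    return float((scores.argmax(axis=1) == labels).mean())


def _grid_edges(rows: int, cols: int):
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols:
                yield (i, i + 1)
            if r + 1 < rows:
                yield (i, i + cols)


def two_blob_graph(blob_size: int = 4) -> SpatialGraph:
    """Two cliques of ``blob_size`` joined by a single bridge edge.

    Its unique minimum balanced 2-cut (value 1) severs the bridge, which makes
    it an exhaustively checkable partitioning oracle.
    """
    n = 2 * blob_size
    edges = []
    for b in (0, blob_size):
        edges += [(i, j) for i in range(b, b + blob_size) for j in range(i + 1, b + blob_size)]
    edges.append((blob_size - 1, blob_size))
    return SpatialGraph.from_edges(n, edges)


def generate_partition_testgraphs(n_max: int = 8, seed: int = 0) -> list[SpatialGraph]:
    """Small named graphs (all with self-loops) for exhaustive partitioner checks."""
    if n_max > 12:
        raise ValueError("n_max must be <= 12 to keep exhaustive oracles tractable")
    rng = np.random.default_rng(seed)
    graphs: list[SpatialGraph] = []
    for n in range(2, n_max + 1):
        graphs.append(SpatialGraph.from_edges(n, [(i, i + 1) for i in range(n - 1)]))  # path
    for n in range(3, n_max + 1):
        cyc = [(i, (i + 1) % n) for i in range(n)]
        graphs.append(SpatialGraph.from_edges(n, cyc))  # cycle
    for n in range(3, n_max + 1):
        graphs.append(SpatialGraph.from_edges(n, [(0, i) for i in range(1, n)]))  # star
    for rows, cols in [(2, 2), (2, 3), (2, 4), (3, 3)]:
        if rows * cols <= n_max:
            graphs.append(SpatialGraph.from_edges(rows * cols, _grid_edges(rows, cols)))
    if n_max >= 8:
        graphs.append(two_blob_graph(n_max // 2))
    for _ in range(4):  # seeded random geometric graphs
        n = int(rng.integers(4, n_max + 1))
        pts = rng.uniform(0, 2.0, size=(n, 2))
        graphs.append(build_radius_graph(pts, r=0.9))
    for g in graphs:
        g.validate()
    return graphs
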