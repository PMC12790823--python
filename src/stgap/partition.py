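"""Multilevel k-way partitioning of the spatial neighbor graph.

Large sections are split into structurally compact, load-balanced subgraphs
that serve as mini-batch units for autoencoder training.  The classical
three-stage scheme is used:

1. *Coarsening*: repeated seeded random matching merges adjacent nodes into
   supernodes (weights accumulate; total node weight is conserved), until the
   graph is small enough for direct partitioning or matching stalls.
2. *Initial partitioning*: degree-based greedy growing on the coarsest graph —
   parts grow from random seeds, absorbing the unassigned neighbor of highest
   degree, until a weight capacity ``cap`` is hit.
3. *Uncoarsening + refinement*: labels are projected level by level back to
   the original graph; at each level, boundary nodes migrate to a neighboring
   part when that strictly reduces the edge cut and respects the capacity.

With the default spot batch size of 256, ``num_parts = 10 N / 256`` and each
subgraph holds roughly ``cap = 25.6`` original spots, so a training batch of
10 subgraphs covers about one batch worth of spots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .graph import SpatialGraph

__all__ = [
    "CoarseLevel",
    "PartitionResult",
    "coarsen_once",
    "coarsen",
    "compute_num_parts",
    "compute_capacity",
    "initial_partition",
    "uncoarsen_labels",
    "refine_boundary",
    "partition_graph",
    "edge_cut",
]

DEFAULT_SPOT_BATCH_SIZE = 256


@dataclass
class CoarseLevel:
    """One coarsening step: the coarsened graph and the fine-to-super map."""

    graph: SpatialGraph
    mapping: np.ndarray  # per-fine-node supernode index

    def __post_init__(self):
        self.mapping = np.asarray(self.mapping, dtype=np.int64)
        nc = self.graph.n_nodes
        if self.mapping.min() < 0 or self.mapping.max() >= nc:
            raise ValueError("mapping out of range")
        if len(np.unique(self.mapping)) != nc:
            raise ValueError("mapping must be surjective onto supernodes")


@dataclass
class PartitionResult:
    """Final per-spot subgraph labels plus the hierarchy and diagnostics."""

    labels: np.ndarray
    num_parts: int
    cap: float
    levels: list[CoarseLevel]
    edge_cut: int
    part_weights: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def part_nodes(self, pid: int) -> np.ndarray:
        return np.flatnonzero(self.labels == pid)


def compute_num_parts(n_spots: int, spot_batch_size: int = DEFAULT_SPOT_BATCH_SIZE) -> int:
    """Number of subgraphs: 10 per batch of ``spot_batch_size`` spots (>= 1).

    Rounded half-up; exact when the batch size divides 10 N.
    """
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")
    if spot_batch_size < 10:
        raise ValueError("spot_batch_size must be >= 10")
    return max(1, int(np.floor(10.0 * n_spots / spot_batch_size + 0.5)))


def compute_capacity(spot_batch_size: int = DEFAULT_SPOT_BATCH_SIZE) -> float:
    """Per-subgraph weight capacity in original spots: batch_size / 10."""
    if spot_batch_size < 10:
        raise ValueError("spot_batch_size must be >= 10")
    return spot_batch_size / 10.0


def edge_cut(g: SpatialGraph, labels: np.ndarray) -> int:
    """Count of non-self-loop edges whose endpoints carry different labels."""
    labels = np.asarray(labels)
    coo = sp.triu(g.adjacency, k=1).tocoo()
    return int((labels[coo.row] != labels[coo.col]).sum())


def coarsen_once(g: SpatialGraph, seed: int, max_weight: float | None = None) -> CoarseLevel:
    """One random heavy-free matching pass.

    Nodes are visited in a seeded random order; each unmatched node merges with
    a uniformly chosen unmatched neighbor (self-loops ineligible; merges that
    would push a supernode past ``max_weight`` are skipped), otherwise it stays
    a singleton.  Supernode weights are the sums of constituent weights, and
    supernodes are adjacent iff any constituent pair was; every supernode keeps
    a self-loop.
    """
    rng = np.random.default_rng(seed)
    n = g.n_nodes
    w = g.node_weight
    mapping = np.full(n, -1, dtype=np.int64)
    next_id = 0
    for u in rng.permutation(n):
        if mapping[u] != -1:
            continue
        nbrs = g.neighbors(u)
        cand = nbrs[(nbrs != u) & (mapping[nbrs] == -1)]
        if max_weight is not None and len(cand):
            cand = cand[w[cand] + w[u] <= max_weight]
        if len(cand):
            v = int(rng.choice(cand))
            mapping[u] = mapping[v] = next_id
        else:
            mapping[u] = next_id
        next_id += 1
    nc = next_id
    # contract: coarse adjacency has an edge wherever any fine pair had one
    M = sp.csr_matrix(
        (np.ones(n, dtype=np.uint8), (np.arange(n), mapping)), shape=(n, nc)
    )
    Ac = (M.T @ g.adjacency @ M).astype(bool).astype(np.uint8)
    wc = np.zeros(nc, dtype=np.int64)
    np.add.at(wc, mapping, w)
    return CoarseLevel(graph=SpatialGraph(Ac, wc), mapping=mapping)


def coarsen(
    g: SpatialGraph,
    num_parts: int,
    cap: float,
    seed: int,
    min_reduction: float = 0.10,
    target_nodes: int | None = None,
) -> list[CoarseLevel]:
    """Coarsen until the graph is small enough to partition directly.

    Stops when the node count drops to ``max(num_parts, ceil(N/cap))`` — by
    then supernodes average about one capacity each — or when a pass shrinks
    the graph by less than ``min_reduction`` (matching has stalled).  Merges
    never create a supernode heavier than ``cap``, so no supernode is
    unsplittable at partition time.  ``target_nodes`` overrides the adaptive
    stop with a fixed classical threshold.
    """
    if num_parts < 1:
        raise ValueError("num_parts must be >= 1")
    N = g.total_weight()
    if target_nodes is None:
        target_nodes = max(num_parts, int(np.ceil(N / cap)))
    levels: list[CoarseLevel] = []
    current = g
    level_seed = seed
    while current.n_nodes > target_nodes:
        lvl = coarsen_once(current, seed=level_seed, max_weight=cap)
        level_seed += 1
        if lvl.graph.n_nodes < num_parts:
            break  # never coarsen below the requested part count
        if lvl.graph.n_nodes >= current.n_nodes * (1 - min_reduction):
            if lvl.graph.n_nodes < current.n_nodes:
                levels.append(lvl)
            break
        levels.append(lvl)
        current = lvl.graph
    return levels


def initial_partition(coarse: SpatialGraph, num_parts: int, cap: float, seed: int) -> np.ndarray:
    """Degree-based greedy growing on the coarsest graph.

    Each part starts at a random unassigned supernode and repeatedly absorbs
    its unassigned neighbor of highest degree (ties: lowest index), stopping
    when the next absorption would exceed ``cap`` or no unassigned neighbor
    remains.  Supernodes left over after ``num_parts`` parts are attached to
    the lightest adjacent part (lightest part overall if isolated).
    """
    n = coarse.n_nodes
    if num_parts > n:
        raise ValueError(f"num_parts={num_parts} exceeds {n} supernodes")
    rng = np.random.default_rng(seed)
    w = coarse.node_weight
    deg = coarse.degree(include_self=False)
    labels = np.full(n, -1, dtype=np.int64)
    part_w = np.zeros(num_parts, dtype=np.float64)

    for pid in range(num_parts):
        unassigned = np.flatnonzero(labels == -1)
        if len(unassigned) == 0:
            break
        start = int(rng.choice(unassigned))
        labels[start] = pid
        part_w[pid] = w[start]
        frontier = {int(v) for v in coarse.neighbors(start) if v != start and labels[v] == -1}
        while frontier:
            v = max(frontier, key=lambda x: (deg[x], -x))
            if part_w[pid] + w[v] > cap:
                break
            labels[v] = pid
            part_w[pid] += w[v]
            frontier.discard(v)
            for u in coarse.neighbors(v):
                if u != v and labels[u] == -1:
                    frontier.add(int(u))
            frontier = {x for x in frontier if labels[x] == -1}

    # leftovers: attach to the lightest adjacent part, sweeping until stable
    changed = True
    while changed:
        changed = False
        for v in np.flatnonzero(labels == -1):
            nbr_parts = {int(labels[u]) for u in coarse.neighbors(v) if labels[u] != -1}
            if nbr_parts:
                pid = min(nbr_parts, key=lambda p: (part_w[p], p))
                labels[v] = pid
                part_w[pid] += w[v]
                changed = True
    for v in np.flatnonzero(labels == -1):  # isolated from all parts
        pid = int(np.lexsort((np.arange(num_parts), part_w))[0])
        labels[v] = pid
        part_w[pid] += w[v]
    return labels


def uncoarsen_labels(labels_coarse: np.ndarray, level: CoarseLevel) -> np.ndarray:
    """Project supernode labels to their constituent fine nodes."""
    labels_coarse = np.asarray(labels_coarse)
    if len(labels_coarse) != level.graph.n_nodes:
        raise ValueError("labels do not cover the level's supernodes")
    return labels_coarse[level.mapping]


def refine_boundary(
    g: SpatialGraph,
    labels: np.ndarray,
    cap: float,
    max_passes: int = 10,
) -> np.ndarray:
    """Greedy boundary migration: move a node to an adjacent part when the
    cut-edge gain is strictly positive and the destination stays within
    ``cap``.  Best gain wins; ties go to the lowest part id.  Passes repeat
    until a full sweep applies no migration or ``max_passes`` is reached.
    The edge cut is non-increasing across the call.
    """
    labels = np.asarray(labels, dtype=np.int64).copy()
    w = g.node_weight
    num_parts = int(labels.max()) + 1
    part_w = np.zeros(num_parts, dtype=np.float64)
    np.add.at(part_w, labels, w.astype(np.float64))

    for _ in range(max_passes):
        moved = False
        for v in range(g.n_nodes):
            nbrs = g.neighbors(v)
            nbrs = nbrs[nbrs != v]
            if len(nbrs) == 0:
                continue
            nl = labels[nbrs]
            cut_before = int((nl != labels[v]).sum())
            if cut_before == 0:
                continue  # not a boundary node
            best = (0, None)  # (gain, part)
            for pid in sorted(set(nl.tolist())):
                if pid == labels[v]:
                    continue
                if part_w[pid] + w[v] > cap:
                    continue
                cut_after = int((nl != pid).sum())
                gain = cut_before - cut_after
                if gain > best[0]:
                    best = (gain, pid)
            if best[1] is not None:
                part_w[labels[v]] -= w[v]
                part_w[best[1]] += w[v]
                labels[v] = best[1]
                moved = True
        if not moved:
            break
    return labels


def partition_graph(
    g: SpatialGraph,
    spot_batch_size: int = DEFAULT_SPOT_BATCH_SIZE,
    seed: int = 0,
    refine_passes: int = 10,
) -> PartitionResult:
    """Full multilevel pipeline: coarsen, grow, project back with refinement."""
    N = g.total_weight()
    num_parts = compute_num_parts(N, spot_batch_size)
    cap = compute_capacity(spot_batch_size)
    s_coarsen, s_init = np.random.default_rng(seed).integers(2**31 - 1, size=2)

    levels = coarsen(g, num_parts, cap, seed=int(s_coarsen))
    coarsest = levels[-1].graph if levels else g
    labels = initial_partition(coarsest, num_parts, cap, seed=int(s_init))

    per_level_cuts = []
    graphs_fine = [g] + [lvl.graph for lvl in levels[:-1]]  # finer graph of each level
    cut_initial = edge_cut(coarsest, labels)
    for lvl, fine_g in zip(reversed(levels), reversed(graphs_fine)):
        labels = uncoarsen_labels(labels, lvl)
        before = edge_cut(fine_g, labels)
        labels = refine_boundary(fine_g, labels, cap, max_passes=refine_passes)
        after = edge_cut(fine_g, labels)
        per_level_cuts.append(
            {"n_nodes": fine_g.n_nodes, "cut_before": before, "cut_after": after}
        )
    if not levels:
        before = edge_cut(g, labels)
        labels = refine_boundary(g, labels, cap, max_passes=refine_passes)
        per_level_cuts.append(
            {"n_nodes": g.n_nodes, "cut_before": before, "cut_after": edge_cut(g, labels)}
        )

    part_w = np.zeros(num_parts, dtype=np.float64)
    np.add.at(part_w, labels, g.node_weight.astype(np.float64))
    overweight = np.flatnonzero(part_w > cap)
    return PartitionResult(
        labels=labels,
        num_parts=num_parts,
        cap=cap,
        levels=levels,
        edge_cut=edge_cut(g, labels),
        part_weights=part_w,
        diagnostics={
            "coarsest_nodes": coarsest.n_nodes,
            "n_levels": len(levels),
            "cut_initial_coarsest": cut_initial,
            "per_level_cuts": per_level_cuts,
            "overweight_parts": overweight.tolist(),
            "level_node_counts": [lvl.graph.n_nodes for lvl in levels],
        },
    )
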