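"""Mini-batch training over partitioned subgraphs and downstream analysis.

Each training batch is the block-diagonal union of several induced subgraphs
(cut edges between subgraphs are dropped, as in independent subgraph
training), so a forward pass over a batch equals running the member subgraphs
separately.  Optimization is Adam with L2 weight decay and global gradient
norm clipping.  After training, the model yields per-spot latent embeddings
and denoised (reconstructed) expression; embeddings are clustered into
spatial domains with k-means or Leiden, and assessed against reference labels
with the standard permutation-invariant metrics.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datasets import (
    SpatialDataset,
    normalize_expression,
    read_spatial_dataset,
    select_hvg,
)
from .gaae import GAAEConfig, GAAEModel, decode, encode, gaae_gradients, init_model
from .graph import SpatialGraph, adaptive_radius, build_radius_graph, mean_neighbor_count
from .partition import PartitionResult, partition_graph

logger = logging.getLogger("stgap")

__all__ = [
    "TrainConfig",
    "DomainAssignment",
    "Batch",
    "make_batches",
    "train",
    "embed_and_denoise",
    "cluster_embeddings",
    "evaluate_clustering",
    "run_pipeline",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the published protocol:
    10 subgraphs per batch, 1000 epochs, Adam lr 1e-3, weight decay 1e-4,
    gradient-norm clip 5)."""

    subgraphs_per_batch: int = 10
    epochs: int = 1000
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    grad_clip_norm: float = 5.0
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self):
        if min(self.subgraphs_per_batch, self.epochs) < 1 or self.learning_rate < 0:
            raise ValueError("invalid training configuration")
        if self.device != "cpu":
            raise ValueError("only cpu execution is supported")


@dataclass
class DomainAssignment:
    """Per-spot outputs: latent embedding, denoised expression, cluster label."""

    embedding: np.ndarray
    denoised: np.ndarray
    cluster: np.ndarray | None = None
    loss_history: np.ndarray | None = None


@dataclass
class Batch:
    """Block-diagonal union of induced subgraphs."""

    node_index: np.ndarray  # original spot indices, concatenated per subgraph
    graph: SpatialGraph
    subgraph_ids: list[int]  # part ids of the member subgraphs


def _induced_subgraphs(
    g: SpatialGraph, p: PartitionResult
) -> list[tuple[int, np.ndarray, SpatialGraph]]:
    out = []
    for pid in range(p.num_parts):
        nodes = p.part_nodes(pid)
        if len(nodes):
            out.append((pid, nodes, g.subgraph(nodes)))
    return out


def make_batches(
    g: SpatialGraph,
    p: PartitionResult,
    subgraphs_per_batch: int,
    seed: int,
    epoch: int,
    induced: list[tuple[int, np.ndarray, SpatialGraph]] | None = None,
) -> list[Batch]:
    """Shuffle subgraphs (seeded per epoch) and group them into batches.

    Every spot appears in exactly one batch; within a batch the subgraphs are
    block-diagonal (only induced edges, self-loops retained, cut edges gone).
    """
    if induced is None:
        induced = _induced_subgraphs(g, p)
    rng = np.random.default_rng([seed, epoch])
    order = rng.permutation(len(induced))
    batches = []
    for start in range(0, len(order), subgraphs_per_batch):
        members = [induced[i] for i in order[start: start + subgraphs_per_batch]]
        nodes = np.concatenate([m[1] for m in members])
        A = sp.block_diag([m[2].adjacency for m in members], format="csr")
        bg = SpatialGraph(A, np.concatenate([m[2].node_weight for m in members]))
        batches.append(
            Batch(node_index=nodes, graph=bg, subgraph_ids=[m[0] for m in members])
        )
    return batches


class _Adam:
    """Adam with decoupled-from-nothing L2 weight decay (decay added to the
    gradient, as in the reference optimizer) and global-norm clipping."""

    def __init__(self, params: list[np.ndarray], lr: float, weight_decay: float, clip: float):
        self.params = params
        self.lr, self.wd, self.clip = lr, weight_decay, clip
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        grads = [gr + self.wd * p for gr, p in zip(grads, self.params)]
        total = np.sqrt(sum(float(np.sum(gr * gr)) for gr in grads))
        if self.clip > 0 and total > self.clip:
            grads = [gr * (self.clip / total) for gr in grads]
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, gr, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * gr
            v *= self.beta2
            v += (1 - self.beta2) * gr * gr
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def train(
    ds: SpatialDataset,
    g: SpatialGraph,
    p: PartitionResult,
    cfg: TrainConfig,
    model_cfg: GAAEConfig | None = None,
) -> tuple[GAAEModel, np.ndarray]:
    """Mini-batch training of the autoencoder over the partitioned graph.

    Returns the trained model and the per-epoch loss history (summed squared
    reconstruction error over all batches; the log additionally reports the
    per-spot mean for cross-run comparability).  Deterministic on cpu for a
    fixed seed.
    """
    X = ds.dense()
    if model_cfg is None:
        model_cfg = GAAEConfig(layer_dims=[ds.n_genes, 128, 64, 30], seed=cfg.seed)
    model = init_model(model_cfg)
    opt = _Adam(
        model.parameters(), cfg.learning_rate, cfg.weight_decay, cfg.grad_clip_norm
    )
    induced = _induced_subgraphs(g, p)
    names = model.parameter_names()
    history = np.zeros(cfg.epochs)
    n_spots = ds.n_spots
    for epoch in range(cfg.epochs):
        total = 0.0
        batches = make_batches(
            g, p, cfg.subgraphs_per_batch, cfg.seed, epoch, induced=induced
        )
        for b, batch in enumerate(batches):
            loss, grads, _, _ = gaae_gradients(X[batch.node_index], batch.graph, model)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite reconstruction loss at epoch {epoch}, batch {b}"
                )
            opt.step([grads[nm] for nm in names])
            total += loss
        history[epoch] = total
        if epoch % max(1, cfg.epochs // 10) == 0:
            logger.info(
                "epoch %d: loss %.4f (%.6f per spot)", epoch, total, total / n_spots
            )
    return model, history


def embed_and_denoise(
    ds: SpatialDataset,
    g: SpatialGraph,
    p: PartitionResult,
    model: GAAEModel,
    full_graph: bool = False,
) -> DomainAssignment:
    """Inference: latent embedding and reconstructed (denoised) expression.

    By default each subgraph is processed independently with its induced
    edges, matching the training regime; ``full_graph=True`` runs a single
    pass over the whole graph instead (cut edges included), when memory
    allows.
    """
    X = ds.dense()
    d_latent = model.config.layer_dims[-1]
    if full_graph:
        Z, cache = encode(X, g, model)
        Xh = decode(Z, g, model, cache)
        return DomainAssignment(embedding=Z, denoised=Xh)
    emb = np.zeros((ds.n_spots, d_latent))
    den = np.zeros((ds.n_spots, ds.n_genes))
    for _, nodes, sub in _induced_subgraphs(g, p):
        Z, cache = encode(X[nodes], sub, model)
        emb[nodes] = Z
        den[nodes] = decode(Z, sub, model, cache)
    return DomainAssignment(embedding=emb, denoised=den)


def cluster_embeddings(
    embedding: np.ndarray,
    method: str = "kmeans",
    k_or_resolution: float = 7,
    seed: int = 0,
) -> np.ndarray:
    """Cluster latent embeddings into spatial domains.

    ``kmeans`` takes a cluster count, ``leiden`` a resolution; label ids are
    arbitrary (defined up to permutation).  Both are seeded.
    """
    embedding = np.asarray(embedding)
    if not np.isfinite(embedding).all():
        raise ValueError("embedding contains non-finite values")
    if method == "kmeans":
        from sklearn.cluster import KMeans

        k = int(k_or_resolution)
        if k > embedding.shape[0]:
            raise ValueError(f"k={k} exceeds n_spots={embedding.shape[0]}")
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        return km.fit_predict(embedding).astype(np.int64)
    if method == "leiden":
        import anndata as ad
        import scanpy as sc

        adata = ad.AnnData(embedding.astype(np.float32))
        sc.pp.neighbors(adata, use_rep="X", random_state=seed)
        sc.tl.leiden(
            adata,
            resolution=float(k_or_resolution),
            random_state=seed,
            flavor="igraph",
            n_iterations=2,
            directed=False,
        )
        return adata.obs["leiden"].astype(int).to_numpy()
    raise ValueError(f"unknown clustering method {method!r}")


def evaluate_clustering(
    pred: np.ndarray, truth: np.ndarray, unlabeled=None
) -> dict[str, float]:
    """ARI / NMI / AMI / homogeneity between predicted and reference labels.

    Spots whose reference equals ``unlabeled`` are excluded from scoring.
    """
    from sklearn import metrics

    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("label vectors differ in length")
    if unlabeled is not None:
        keep = truth != unlabeled
        if not keep.any():
            raise ValueError("all reference labels are unlabeled")
        pred, truth = pred[keep], truth[keep]
    return {
        "ARI": float(metrics.adjusted_rand_score(truth, pred)),
        "NMI": float(metrics.normalized_mutual_info_score(truth, pred)),
        "AMI": float(metrics.adjusted_mutual_info_score(truth, pred)),
        "homogeneity": float(metrics.homogeneity_score(truth, pred)),
    }


DEFAULT_PIPELINE_CONFIG = {
    "target_sum": 1e4,
    "log1p": True,
    "n_hvg": 3000,
    "radius": "auto",
    "target_neighbors": (10.0, 30.0),
    "spot_batch_size": 256,
    "seed": 0,
    "epochs": 1000,
    "subgraphs_per_batch": 10,
    "learning_rate": 1e-3,
    "weight_decay": 1e-4,
    "grad_clip_norm": 5.0,
    "latent_dim": 30,
    "hidden_dims": (128, 64),
    "activation": "elu",
    "cluster_method": "kmeans",
    "n_clusters": 7,
    "full_graph_inference": False,
}


def run_pipeline(config, out_dir: str | None = None) -> DomainAssignment:
    """End-to-end run: preprocess -> graph -> partition -> train -> embed,
    denoise, cluster; artifacts written to ``out_dir``.

    ``config`` is a dict (or a path to a YAML file) overriding
    :data:`DEFAULT_PIPELINE_CONFIG`; the input is given either as
    ``{"input": PATH, "format": h5ad|mtx_dir|csv_pair}`` or as a pre-built
    ``SpatialDataset`` under ``"dataset"``.  Each stage failure is re-raised
    with the stage name.
    """
    if isinstance(config, (str, os.PathLike)):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = {**DEFAULT_PIPELINE_CONFIG, **dict(config)}
    if out_dir is None:
        out_dir = cfg.get("out_dir", "stgap_out")
    os.makedirs(out_dir, exist_ok=True)

    def stage(name, fn):
        try:
            result = fn()
        except Exception as e:
            raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e
        logger.info("stage %s done", name)
        return result

    def _load():
        if "dataset" in cfg:
            ds = cfg["dataset"]
        else:
            ds = read_spatial_dataset(cfg["input"], cfg["format"])
        ds = normalize_expression(ds, cfg["target_sum"], cfg["log1p"])
        return select_hvg(ds, min(cfg["n_hvg"], ds.n_genes))

    ds = stage("preprocess", _load)

    def _graph():
        r = cfg["radius"]
        if r == "auto":
            r = adaptive_radius(ds.coords, tuple(cfg["target_neighbors"]))
        g = build_radius_graph(ds.coords, float(r))
        return g, float(r)

    g, radius = stage("graph", _graph)

    p = stage(
        "partition",
        lambda: partition_graph(g, cfg["spot_batch_size"], seed=cfg["seed"]),
    )

    tcfg = TrainConfig(
        subgraphs_per_batch=cfg["subgraphs_per_batch"],
        epochs=cfg["epochs"],
        learning_rate=cfg["learning_rate"],
        weight_decay=cfg["weight_decay"],
        grad_clip_norm=cfg["grad_clip_norm"],
        seed=cfg["seed"],
    )
    mcfg = GAAEConfig(
        layer_dims=[ds.n_genes, *cfg["hidden_dims"], cfg["latent_dim"]],
        activation=cfg["activation"],
        seed=cfg["seed"],
    )
    model, history = stage("train", lambda: train(ds, g, p, tcfg, mcfg))

    assign = stage(
        "embed",
        lambda: embed_and_denoise(ds, g, p, model, cfg["full_graph_inference"]),
    )
    labels = stage(
        "cluster",
        lambda: cluster_embeddings(
            assign.embedding,
            cfg["cluster_method"],
            cfg["n_clusters"]
            if cfg["cluster_method"] == "kmeans"
            else cfg.get("resolution", 1.0),
            seed=cfg["seed"],
        ),
    )
    assign.cluster = labels
    assign.loss_history = history

    # artifacts
    spot_ids = ds.spot_ids.astype(str)
    pd.DataFrame(
        assign.embedding, index=pd.Index(spot_ids, name="spot_id")
    ).to_csv(os.path.join(out_dir, "embedding.csv"))
    from scipy.io import mmwrite

    mmwrite(os.path.join(out_dir, "denoised.mtx"), sp.coo_matrix(assign.denoised))
    pd.DataFrame(
        {"domain": labels}, index=pd.Index(spot_ids, name="spot_id")
    ).to_csv(os.path.join(out_dir, "labels.csv"))
    pd.DataFrame(
        {"epoch": np.arange(len(history)), "loss": history,
         "loss_per_spot": history / ds.n_spots}
    ).to_csv(os.path.join(out_dir, "loss.csv"), index=False)
    diag = {
        "radius": radius,
        "mean_neighbors": mean_neighbor_count(g),
        "num_parts": p.num_parts,
        "cap": p.cap,
        "edge_cut": p.edge_cut,
        "partition": p.diagnostics,
        "resolved_config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in cfg.items()
            if k != "dataset"
        },
    }
    with open(os.path.join(out_dir, "diagnostics.json"), "w") as fh:
        json.dump(diag, fh, indent=2, default=str)
    return assign
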