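"""Graph attention autoencoder with a weight-tied symmetric decoder.

The encoder stacks L layers.  Layers 1..L-1 are graph attention layers: node
i aggregates its (self-inclusive) neighborhood, each neighbor j weighted by a
softmax-normalized coefficient

    alpha_ij = softmax_{j in N_i}( sigmoid( a^T [W z_i || W z_j] ) ),

and applies a nonlinearity.  The final layer is attention-free linear and
produces the latent embedding.  The decoder mirrors the encoder exactly:
layer k reuses the *transposed* encoder weight W_k^T and the encoder's cached
attention coefficients for layer k — no decoder weight is a free parameter.
An optional linear head (X_hat = Z W_d + b) is available as an alternative
reconstruction path.

There is no autodiff dependency: forward passes cache intermediates and
``gaae_gradients`` implements exact reverse-mode differentiation of the
summed squared-error reconstruction loss, including the dependence of the
attention coefficients on W and a through both the encoder and the decoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.special import expit

from .graph import SpatialGraph

__all__ = [
    "GAAEConfig",
    "GAAEModel",
    "AttentionCache",
    "init_model",
    "attention_coefficients",
    "encode",
    "decode",
    "reconstruction_loss",
    "gaae_gradients",
    "save_model",
    "load_model",
]

_ACTIVATIONS = ("elu", "relu", "identity")
CHECKPOINT_SCHEMA = 1


def _act(u: np.ndarray, kind: str) -> np.ndarray:
    if kind == "elu":
        return np.where(u > 0, u, np.expm1(np.minimum(u, 0.0)))
    if kind == "relu":
        return np.maximum(u, 0.0)
    return u


def _act_grad(u: np.ndarray, kind: str) -> np.ndarray:
    if kind == "elu":
        return np.where(u > 0, 1.0, np.exp(np.minimum(u, 0.0)))
    if kind == "relu":
        return (u > 0).astype(u.dtype)
    return np.ones_like(u)


@dataclass
class GAAEConfig:
    """Architecture: ``layer_dims = [d_in, hidden..., d_latent]``.

    Default depth is three layers with a 30-dimensional latent space; the
    hidden activation applies to all but the latent (and final reconstruction)
    layer, which stay linear.
    """

    layer_dims: list[int]
    activation: str = "elu"
    seed: int = 0
    linear_head: bool = False  # reconstruct via X_hat = Z W_d + b instead of the mirror

    def __post_init__(self):
        if len(self.layer_dims) < 2 or any(d < 1 for d in self.layer_dims):
            raise ValueError("layer_dims needs >= 2 entries, all >= 1")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")

    @property
    def n_layers(self) -> int:
        return len(self.layer_dims) - 1


@dataclass
class GAAEModel:
    """Parameters: per-layer weights ``W[k]`` and attention vectors ``a[k]``.

    ``W[k]`` has shape (d_k, d_{k+1}); ``a[k]`` has length 2 d_{k+1} and
    exists only for the attention layers k = 0..L-2.  The decoder owns no
    parameters: it reads the same ``W`` transposed.
    """

    W: list[np.ndarray]
    a: list[np.ndarray]
    config: GAAEConfig
    head_Wd: np.ndarray | None = None
    head_b: np.ndarray | None = None

    def parameters(self) -> list[np.ndarray]:
        ps = list(self.W) + list(self.a)
        if self.config.linear_head:
            ps += [self.head_Wd, self.head_b]
        return ps

    def parameter_names(self) -> list[str]:
        names = [f"W{k+1}" for k in range(len(self.W))] + [
            f"a{k+1}" for k in range(len(self.a))
        ]
        if self.config.linear_head:
            names += ["head_Wd", "head_b"]
        return names


@dataclass
class AttentionCache:
    """Per-forward-pass intermediates, keyed to one graph.

    ``alpha`` holds, for each attention layer, the edge-aligned coefficient
    array in the CSR order of the graph (rows sum to 1).  The rest is what
    backpropagation needs.
    """

    n_nodes: int
    indptr: np.ndarray
    indices: np.ndarray
    alpha: list[np.ndarray] = field(default_factory=list)
    e: list[np.ndarray] = field(default_factory=list)  # sigmoid scores per edge
    Z_in: list[np.ndarray] = field(default_factory=list)  # input to each attention layer
    S: list[np.ndarray] = field(default_factory=list)  # Z_in @ W per attention layer
    U: list[np.ndarray] = field(default_factory=list)  # pre-activation aggregate
    Z_pre_latent: np.ndarray | None = None  # input to the final linear layer
    V_latent: np.ndarray | None = None  # pre-activation of the latent layer
    # decoder-side caches (filled by decode)
    dec_T: np.ndarray | None = None  # pre-activation of the first mirror step
    dec_Hin: list[np.ndarray] = field(default_factory=list)
    dec_S: list[np.ndarray] = field(default_factory=list)
    dec_U: list[np.ndarray] = field(default_factory=list)

    def matches(self, g: SpatialGraph) -> bool:
        return (
            self.n_nodes == g.n_nodes
            and len(self.indices) == g.n_directed_edges
            and np.array_equal(self.indptr, g.indptr)
        )

    def alpha_matrix(self, k: int) -> sp.csr_matrix:
        return sp.csr_matrix(
            (self.alpha[k], self.indices, self.indptr), shape=(self.n_nodes, self.n_nodes)
        )


def init_model(cfg: GAAEConfig) -> GAAEModel:
    """Glorot-initialized parameters, deterministic for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    dims = cfg.layer_dims
    W, a = [], []
    for k in range(cfg.n_layers):
        fan_in, fan_out = dims[k], dims[k + 1]
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        W.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        if k < cfg.n_layers - 1:
            a.append(rng.uniform(-limit, limit, size=2 * fan_out))
    head_Wd = head_b = None
    if cfg.linear_head:
        limit = np.sqrt(6.0 / (dims[-1] + dims[0]))
        head_Wd = rng.uniform(-limit, limit, size=(dims[-1], dims[0]))
        head_b = np.zeros(dims[0])
    return GAAEModel(W=W, a=a, config=cfg, head_Wd=head_Wd, head_b=head_b)


def _row_reduce(values: np.ndarray, indptr: np.ndarray, op) -> np.ndarray:
    """Segment reduction over CSR rows (every row non-empty: self-loops)."""
    return op.reduceat(values, indptr[:-1])


def _segment_softmax(scores: np.ndarray, indptr: np.ndarray, row: np.ndarray) -> np.ndarray:
    m = _row_reduce(scores, indptr, np.maximum)
    ex = np.exp(scores - m[row])
    denom = _row_reduce(ex, indptr, np.add)
    return ex / denom[row]


def _edge_rows(indptr: np.ndarray) -> np.ndarray:
    return np.repeat(np.arange(len(indptr) - 1), np.diff(indptr))


def attention_coefficients(
    Z_prev: np.ndarray,
    W_k: np.ndarray,
    a_k: np.ndarray,
    g: SpatialGraph,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Edge-aligned attention coefficients for one layer.

    Returns ``(alpha, e, S)`` where ``alpha``/``e`` align with the graph's CSR
    edge order and ``S = Z_prev @ W_k``.  Non-neighbors never enter the
    softmax, so each node's coefficients sum to 1 over its self-inclusive
    neighborhood.
    """
    S = Z_prev @ W_k
    d = W_k.shape[1]
    a_l, a_r = a_k[:d], a_k[d:]
    row = _edge_rows(g.indptr)
    col = g.indices
    scores = expit((S @ a_l)[row] + (S @ a_r)[col])
    alpha = _segment_softmax(scores, g.indptr, row)
    return alpha, scores, S


def encode(
    X: np.ndarray, g: SpatialGraph, model: GAAEModel
) -> tuple[np.ndarray, AttentionCache]:
    """Forward pass through the encoder; caches everything the decoder and
    backward pass need."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] != g.n_nodes:
        raise ValueError(f"X has {X.shape[0]} rows for a graph of {g.n_nodes} nodes")
    if X.shape[1] != model.config.layer_dims[0]:
        raise ValueError(
            f"X has {X.shape[1]} features, model expects {model.config.layer_dims[0]}"
        )
    cfg = model.config
    cache = AttentionCache(n_nodes=g.n_nodes, indptr=g.indptr, indices=g.indices)
    Z = X
    for k in range(cfg.n_layers - 1):
        alpha, e, S = attention_coefficients(Z, model.W[k], model.a[k], g)
        cache.Z_in.append(Z)
        cache.S.append(S)
        cache.alpha.append(alpha)
        cache.e.append(e)
        P = cache.alpha_matrix(k)
        U = P @ S
        cache.U.append(U)
        Z = _act(U, cfg.activation)
    cache.Z_pre_latent = Z
    V = Z @ model.W[-1]
    cache.V_latent = V
    return V, cache  # latent layer is linear (identity activation)


def decode(
    Z_latent: np.ndarray,
    g: SpatialGraph,
    model: GAAEModel,
    cache: AttentionCache,
) -> np.ndarray:
    """Mirror decoder: transposed weights, reused attention.

    The first step inverts the attention-free latent layer; then attention
    layers run in reverse, each aggregating with the encoder's cached alpha
    for that layer.  The final reconstruction layer is linear.  With the
    ``linear_head`` config the reconstruction is instead ``Z W_d + b``.
    """
    if not cache.matches(g):
        raise ValueError("stale attention cache: graph does not match")
    cfg = model.config
    if cfg.linear_head:
        return Z_latent @ model.head_Wd + model.head_b
    T = Z_latent @ model.W[-1].T
    cache.dec_T = T
    H = _act(T, cfg.activation) if cfg.n_layers > 1 else T
    cache.dec_Hin, cache.dec_S, cache.dec_U = [], [], []
    for k in range(cfg.n_layers - 2, -1, -1):
        cache.dec_Hin.append(H)
        Sd = H @ model.W[k].T
        cache.dec_S.append(Sd)
        Ud = cache.alpha_matrix(k) @ Sd
        cache.dec_U.append(Ud)
        H = _act(Ud, cfg.activation) if k > 0 else Ud  # output layer linear
    return H


def reconstruction_loss(X: np.ndarray, X_hat: np.ndarray) -> float:
    """Summed squared Frobenius reconstruction error."""
    X, X_hat = np.asarray(X), np.asarray(X_hat)
    if X.shape != X_hat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {X_hat.shape}")
    diff = X - X_hat
    return float(np.sum(diff * diff))


def _attention_backward(
    dalpha: np.ndarray,
    alpha: np.ndarray,
    e: np.ndarray,
    S: np.ndarray,
    a_k: np.ndarray,
    indptr: np.ndarray,
    row: np.ndarray,
    col: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Backprop through alpha = softmax(sigmoid(a^T [S_i || S_j])).

    Returns (dS contribution, da_k)."""
    d = S.shape[1]
    a_l, a_r = a_k[:d], a_k[d:]
    rowdot = np.add.reduceat(alpha * dalpha, indptr[:-1])
    dE = alpha * (dalpha - rowdot[row])
    dc = dE * e * (1.0 - e)  # sigmoid'
    dsl = np.add.reduceat(dc, indptr[:-1])  # per-row scalar
    dsr = np.zeros(len(indptr) - 1)
    np.add.at(dsr, col, dc)
    dS = dsl[:, None] * a_l[None, :] + dsr[:, None] * a_r[None, :]
    da = np.concatenate([S.T @ dsl, S.T @ dsr])
    return dS, da


def gaae_gradients(
    X: np.ndarray,
    g: SpatialGraph,
    model: GAAEModel,
) -> tuple[float, dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Loss and exact gradients for one forward/backward pass.

    Runs encode + decode, computes the summed squared-error loss, and returns
    ``(loss, grads, Z_latent, X_hat)`` where ``grads`` maps parameter names
    (``W1..WL``, ``a1..a(L-1)``, optionally the linear head) to arrays of the
    parameter's shape.  The gradient accounts for every path, including the
    attention coefficients' dependence on the parameters and their reuse in
    the decoder.
    """
    cfg = model.config
    Z_latent, cache = encode(X, g, model)
    X_hat = decode(Z_latent, g, model, cache)
    loss = reconstruction_loss(X, X_hat)

    dW = [np.zeros_like(w) for w in model.W]
    da = [np.zeros_like(v) for v in model.a]
    dalpha_extra = [np.zeros_like(al) for al in cache.alpha]
    row = _edge_rows(cache.indptr)
    col = cache.indices

    G = 2.0 * (X_hat - X)  # d loss / d X_hat

    if cfg.linear_head:
        d_head_Wd = Z_latent.T @ G
        d_head_b = G.sum(axis=0)
        dZ_latent = G @ model.head_Wd.T
    else:
        # decoder backward: layers were applied k = L-2 .. 0 (lists in that order)
        for idx in range(len(cache.dec_S) - 1, -1, -1):
            k = cfg.n_layers - 2 - idx  # encoder-layer index this step mirrors
            Ud, Sd, Hin = cache.dec_U[idx], cache.dec_S[idx], cache.dec_Hin[idx]
            dUd = G if k == 0 else G * _act_grad(Ud, cfg.activation)
            # Ud = P_k @ Sd: grad wrt alpha and Sd
            dalpha_extra[k] += np.einsum("ij,ij->i", dUd[row], Sd[col])
            P = cache.alpha_matrix(k)
            dSd = P.T @ dUd
            # Sd = Hin @ W_k^T
            dW[k] += dSd.T @ Hin
            G = dSd @ model.W[k]
        # first mirror step: T = Z_latent @ W_L^T, H0 = act(T) (or T if L == 1)
        T = cache.dec_T
        dT = G * _act_grad(T, cfg.activation) if cfg.n_layers > 1 else G
        dW[-1] += dT.T @ Z_latent
        dZ_latent = dT @ model.W[-1]

    # encoder backward
    # latent layer: V = Z_pre_latent @ W_L (linear)
    dV = dZ_latent
    dW[-1] += cache.Z_pre_latent.T @ dV
    G = dV @ model.W[-1].T
    for k in range(cfg.n_layers - 2, -1, -1):
        U, S, Zin = cache.U[k], cache.S[k], cache.Z_in[k]
        alpha, e = cache.alpha[k], cache.e[k]
        dU = G * _act_grad(U, cfg.activation)
        dalpha = np.einsum("ij,ij->i", dU[row], S[col]) + dalpha_extra[k]
        P = cache.alpha_matrix(k)
        dS = P.T @ dU
        dS_att, da_k = _attention_backward(
            dalpha, alpha, e, S, model.a[k], cache.indptr, row, col
        )
        dS = dS + dS_att
        da[k] += da_k
        dW[k] += Zin.T @ dS
        G = dS @ model.W[k].T

    grads = {f"W{k+1}": dW[k] for k in range(len(dW))}
    grads.update({f"a{k+1}": da[k] for k in range(len(da))})
    if cfg.linear_head:
        grads["head_Wd"] = d_head_Wd
        grads["head_b"] = d_head_b
    return loss, grads, Z_latent, X_hat


def save_model(model: GAAEModel, path) -> None:
    """Single-archive checkpoint: schema, config, and all parameter tensors."""
    arrays = {f"W{k}": w for k, w in enumerate(model.W)}
    arrays.update({f"a{k}": v for k, v in enumerate(model.a)})
    if model.config.linear_head:
        arrays["head_Wd"] = model.head_Wd
        arrays["head_b"] = model.head_b
    np.savez(
        path,
        schema=CHECKPOINT_SCHEMA,
        layer_dims=np.array(model.config.layer_dims),
        activation=model.config.activation,
        seed=model.config.seed,
        linear_head=model.config.linear_head,
        **arrays,
    )


def load_model(path) -> GAAEModel:
    with np.load(path, allow_pickle=False) as z:
        if int(z["schema"]) != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {z['schema']}")
        cfg = GAAEConfig(
            layer_dims=[int(d) for d in z["layer_dims"]],
            activation=str(z["activation"]),
            seed=int(z["seed"]),
            linear_head=bool(z["linear_head"]),
        )
        model = GAAEModel(
            W=[z[f"W{k}"] for k in range(cfg.n_layers)],
            a=[z[f"a{k}"] for k in range(cfg.n_layers - 1)],
            config=cfg,
            head_Wd=z["head_Wd"] if cfg.linear_head else None,
            head_b=z["head_b"] if cfg.linear_head else None,
        )
    return model
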