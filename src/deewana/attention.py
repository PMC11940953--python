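"""Self-attention neighbor weighting trained by distance regression.

The learned alternative to the closed-form weights: a one-head or
multi-head scaled dot-product self-attention over the matrix
I = [r_center; r_v1; ...; r_vm] (zero-padded to n = 1 + max_neighbors
rows), followed by a three-layer MLP (n*d_model -> n*d_model/2 -> n-1)
that predicts the center-neighbor Euclidean distances.  Training
minimizes the squared error between predicted and true embedding-space
distances — an unsupervised, geometry-aware signal that requires no node
labels.  The aggregation weights are read off the attention map itself:
the center row, restricted to real-neighbor columns and renormalized;
multi-head weights are the mean of the per-head rows.

Everything is plain numpy with manual gradients and Adam, single-threaded
and bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .embedding import EmbeddingMatrix
from .weighting import NeighborContext, WeightVector

__all__ = [
    "AttentionModel",
    "TrainingBatch",
    "build_attention_model",
    "build_batch",
    "attention_forward",
    "train_attention",
    "attention_weights",
    "save_model",
    "load_model",
]

_NEG = -1e30  # masked logit; exp underflows to exactly 0


@dataclass
class AttentionModel:
    """Parameters of the attention + MLP distance regressor.

    ``params`` holds: Wq, Wk, Wv of shape (h, d_model, d_k); Wout of
    shape (h*d_v, d_model) for h > 1; MLP weights W1, b1, W2, b2.
    """

    d_model: int
    heads: int
    max_neighbors: int
    seed: int
    params: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def d_k(self) -> int:
        return self.d_model // self.heads

    @property
    def d_v(self) -> int:
        return self.d_model // self.heads

    @property
    def n(self) -> int:
        """Rows of the input matrix I: center + max_neighbors slots."""
        return self.max_neighbors + 1

    @property
    def mode(self) -> str:
        return "1H" if self.heads == 1 else "MH"


@dataclass
class TrainingBatch:
    """Padded context matrices and distance targets.

    ``inputs`` is (B, n, d_model) with row 0 the center vector; ``mask``
    (B, n) flags real rows; ``targets``/``target_mask`` are (B, n-1)
    distances for real neighbor slots.
    """

    inputs: np.ndarray
    mask: np.ndarray
    targets: np.ndarray
    target_mask: np.ndarray

    def __post_init__(self) -> None:
        b, n, _ = self.inputs.shape
        if self.mask.shape != (b, n):
            raise ValueError("mask shape mismatch")
        if self.targets.shape != (b, n - 1) or self.target_mask.shape != (b, n - 1):
            raise ValueError("target shape mismatch")

    def __len__(self) -> int:
        return self.inputs.shape[0]


def build_attention_model(
    d_model: int = 128,
    heads: int = 4,
    max_neighbors: int = 10,
    seed: int = 0,
) -> AttentionModel:
    """Initialize an untrained model with seeded scaled-Gaussian weights."""
    if d_model % heads != 0:
        raise ValueError(f"d_model={d_model} not divisible by heads={heads}")
    rng = np.random.default_rng(seed)
    d_k = d_model // heads
    n = max_neighbors + 1
    hidden = (n * d_model) // 2

    def init(*shape):
        fan_in = shape[-2] if len(shape) >= 2 else shape[-1]
        return rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)

    params = {
        "Wq": init(heads, d_model, d_k),
        "Wk": init(heads, d_model, d_k),
        "Wv": init(heads, d_model, d_k),
        "W1": init(n * d_model, hidden),
        "b1": np.zeros(hidden),
        "W2": init(hidden, n - 1),
        "b2": np.zeros(n - 1),
    }
    if heads > 1:
        params["Wout"] = init(heads * d_k, d_model)
    return AttentionModel(d_model, heads, max_neighbors, seed, params)


def build_batch(
    contexts: list[NeighborContext],
    emb: EmbeddingMatrix,
    max_neighbors: int,
) -> TrainingBatch:
    """Pack contexts into padded input matrices with distance targets."""
    usable = [c for c in contexts if c.neighbors]
    if not usable:
        raise ValueError("no context has neighbors")
    b, n, d = len(usable), max_neighbors + 1, emb.d_model
    inputs = np.zeros((b, n, d))
    mask = np.zeros((b, n), dtype=bool)
    targets = np.zeros((b, n - 1))
    tmask = np.zeros((b, n - 1), dtype=bool)
    for i, ctx in enumerate(usable):
        k = len(ctx.neighbors)
        if k > max_neighbors:
            raise ValueError(
                f"context of {ctx.center!r} has {k} > {max_neighbors} neighbors"
            )
        inputs[i, 0] = emb.row(ctx.center)
        inputs[i, 1:k + 1] = emb.rows(ctx.neighbors)
        mask[i, :k + 1] = True
        targets[i, :k] = ctx.distances
        tmask[i, :k] = True
    return TrainingBatch(inputs, mask, targets, tmask)


def _forward(model: AttentionModel, batch: TrainingBatch, need_grad: bool = False):
    """Attention + MLP forward pass; returns (pred, alpha[, cache])."""
    p = model.params
    I, mask = batch.inputs, batch.mask
    B, n, D = I.shape
    if n != model.n or D != model.d_model:
        raise ValueError(
            f"batch shaped {(n, D)} but model expects {(model.n, model.d_model)}"
        )
    h, d_k = model.heads, model.d_k

    Q = np.einsum("bnd,hdk->bhnk", I, p["Wq"])
    K = np.einsum("bnd,hdk->bhnk", I, p["Wk"])
    V = np.einsum("bnd,hdk->bhnk", I, p["Wv"])
    S = np.einsum("bhnk,bhmk->bhnm", Q, K) / np.sqrt(d_k)
    S = np.where(mask[:, None, None, :], S, _NEG)  # mask padded keys
    S = S - S.max(axis=-1, keepdims=True)
    E = np.exp(S)
    A = E / E.sum(axis=-1, keepdims=True)  # (B, h, n, n)
    O = np.einsum("bhnm,bhmk->bhnk", A, V)

    Ocat = O.transpose(0, 2, 1, 3).reshape(B, n, h * model.d_v)
    Z = Ocat @ p["Wout"] if h > 1 else Ocat
    Z = Z * mask[:, :, None]  # padded rows contribute nothing downstream

    x = Z.reshape(B, n * D)
    a1 = x @ p["W1"] + p["b1"]
    h1 = np.maximum(a1, 0.0)
    pred = h1 @ p["W2"] + p["b2"]  # (B, n-1) estimated distances

    # aggregation weights: center row, mean over heads, neighbor columns
    alpha = A[:, :, 0, 1:].mean(axis=1)  # (B, n-1)
    alpha = alpha * batch.target_mask
    alpha = alpha / alpha.sum(axis=-1, keepdims=True)

    if not need_grad:
        return pred, alpha
    cache = dict(I=I, mask=mask, Q=Q, K=K, V=V, A=A, Ocat=Ocat, x=x, a1=a1, h1=h1)
    return pred, alpha, cache


def attention_forward(model: AttentionModel, batch: TrainingBatch):
    """Predicted distances and per-context attention weights (pure, no state)."""
    pred, alpha = _forward(model, batch)
    return pred * batch.target_mask, alpha


def _loss_and_grads(model: AttentionModel, batch: TrainingBatch):
    """Masked MSE between predicted and true distances, with parameter grads."""
    p = model.params
    pred, _, c = _forward(model, batch, need_grad=True)
    tm = batch.target_mask
    count = tm.sum()
    resid = (pred - batch.targets) * tm
    loss = float((resid ** 2).sum() / count)

    h, d_k = model.heads, model.d_k
    B, n, D = c["I"].shape
    g: dict[str, np.ndarray] = {}

    dpred = 2.0 * resid / count
    g["W2"] = c["h1"].T @ dpred
    g["b2"] = dpred.sum(axis=0)
    dh1 = dpred @ p["W2"].T
    da1 = dh1 * (c["a1"] > 0)
    g["W1"] = c["x"].T @ da1
    g["b1"] = da1.sum(axis=0)
    dx = da1 @ p["W1"].T

    dZ = dx.reshape(B, n, D) * c["mask"][:, :, None]
    if h > 1:
        g["Wout"] = np.einsum("bnc,bnd->cd", c["Ocat"], dZ)
        dOcat = dZ @ p["Wout"].T
    else:
        dOcat = dZ
    dO = dOcat.reshape(B, n, h, model.d_v).transpose(0, 2, 1, 3)

    A, V, Q, K = c["A"], c["V"], c["Q"], c["K"]
    dA = np.einsum("bhnk,bhmk->bhnm", dO, V)
    dV = np.einsum("bhnm,bhnk->bhmk", A, dO)
    dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
    dQ = np.einsum("bhnm,bhmk->bhnk", dS, K) / np.sqrt(d_k)
    dK = np.einsum("bhnm,bhnk->bhmk", dS, Q) / np.sqrt(d_k)

    I = c["I"]
    g["Wq"] = np.einsum("bnd,bhnk->hdk", I, dQ)
    g["Wk"] = np.einsum("bmd,bhmk->hdk", I, dK)
    g["Wv"] = np.einsum("bmd,bhmk->hdk", I, dV)
    return loss, g


def train_attention(
    model: AttentionModel,
    contexts: list[NeighborContext],
    emb: EmbeddingMatrix,
    epochs: int = 100,
    learning_rate: float = 1e-3,
    batch_size: int = 32,
    seed: int = 0,
) -> tuple[AttentionModel, list[float]]:
    """Train in place by seeded mini-batch Adam on the distance-regression loss.

    Returns the model and the per-epoch mean training loss (empty for
    ``epochs=0``; parameters are then untouched).
    """
    if not contexts:
        raise ValueError("no training contexts")
    full = build_batch(contexts, emb, model.max_neighbors)
    rng = np.random.default_rng(seed)

    m_t = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_t = {k: np.zeros_like(v) for k, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    history: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(len(full))
        batch_losses = []
        for start in range(0, len(full), batch_size):
            idx = order[start:start + batch_size]
            sub = TrainingBatch(
                full.inputs[idx], full.mask[idx],
                full.targets[idx], full.target_mask[idx],
            )
            loss, grads = _loss_and_grads(model, sub)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss {loss}; lower the learning rate"
                )
            batch_losses.append(loss)
            step += 1
            for k, grad in grads.items():
                m_t[k] = beta1 * m_t[k] + (1 - beta1) * grad
                v_t[k] = beta2 * v_t[k] + (1 - beta2) * grad ** 2
                m_hat = m_t[k] / (1 - beta1 ** step)
                v_hat = v_t[k] / (1 - beta2 ** step)
                model.params[k] -= learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        history.append(float(np.mean(batch_losses)))
    return model, history


def attention_weights(
    model: AttentionModel, ctx: NeighborContext, emb: EmbeddingMatrix
) -> WeightVector:
    """Aggregation weights for one context from the (trained) model."""
    if not ctx.neighbors:
        raise ValueError(f"node {ctx.center!r} has no neighbors")
    batch = build_batch([ctx], emb, model.max_neighbors)
    _, alpha = _forward(model, batch)
    k = len(ctx.neighbors)
    return WeightVector(alpha[0, :k], model.mode)


def save_model(model: AttentionModel, path: str | Path) -> None:
    """Serialize to a single self-describing .npz archive."""
    np.savez(
        path,
        d_model=model.d_model,
        heads=model.heads,
        max_neighbors=model.max_neighbors,
        seed=model.seed,
        **model.params,
    )


def load_model(path: str | Path) -> AttentionModel:
    with np.load(path) as data:
        meta = {k: int(data[k]) for k in ("d_model", "heads", "max_neighbors", "seed")}
        params = {
            k: data[k]
            for k in data.files
            if k not in ("d_model", "heads", "max_neighbors", "seed")
        }
    return AttentionModel(**meta, params=params)
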