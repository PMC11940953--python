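"""Neighbor contexts and distance-based aggregation weights.

A node's one-hop neighborhood (truncated to at most ``max_neighbors``,
default 10) together with the center-neighbor Euclidean distances in
embedding space forms a :class:`NeighborContext`.  Aggregation weights
over that context come from one of two families:

* **non-learning** (modes ``N`` and ``F``): each distance d is squashed by
  a sigmoid — mode N uses d' = 1/(1+e^d) (closer neighbors weigh more),
  mode F uses d' = 1/(1+e^-d) (farther neighbors weigh more) — and the
  weights are softmax(e^{d'}) over the neighborhood.  Note the N map
  sends d >= 0 into (0, 0.5]; the formula is applied exactly as defined.
* **self-attention** (modes ``1H`` and ``MH``): learned weights from the
  attention module, trained to regress the same distances.

Hybrid policies (``1H+N``, ``MH+N``) use attention for low-degree nodes
and fall back to the cheap non-learning mode N when the full degree
exceeds a threshold, which is how the method scales to hub-heavy graphs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import EmbeddingMatrix
from .graph_io import Graph

__all__ = [
    "NeighborContext",
    "WeightVector",
    "neighbor_context",
    "all_neighbor_contexts",
    "normalize_distance",
    "nonlearning_weights",
    "select_weighting",
    "POLICIES",
]

POLICIES = ("N", "F", "1H", "MH", "1H+N", "MH+N")


@dataclass
class NeighborContext:
    """A center node, its (possibly truncated) neighbor sample and distances.

    ``full_degree`` is the degree before truncation; ``len(neighbors)`` is
    ``min(full_degree, max_neighbors)``.  Distances are Euclidean norms
    ``||r_center - r_v||_2`` in the self-representational embedding.
    """

    center: str
    neighbors: list[str]
    distances: np.ndarray
    max_neighbors: int
    full_degree: int

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=np.float64)
        if len(self.neighbors) != self.distances.shape[0]:
            raise ValueError("neighbors and distances misaligned")
        if np.any(self.distances < 0):
            raise ValueError("negative distance")

    @property
    def is_isolated(self) -> bool:
        return self.full_degree == 0


@dataclass
class WeightVector:
    """Per-neighbor aggregation weights (sum to 1), tagged with the mode used."""

    weights: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.mode not in POLICIES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.weights.size and not np.isclose(self.weights.sum(), 1.0, atol=1e-9):
            raise ValueError(f"weights sum to {self.weights.sum()}, not 1")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be strictly positive")

    def __len__(self) -> int:
        return self.weights.size


def neighbor_context(
    graph: Graph,
    emb: EmbeddingMatrix,
    center: str,
    max_neighbors: int = 10,
    seed: int = 0,
) -> NeighborContext:
    """Build the neighbor context of ``center``.

    If the degree exceeds ``max_neighbors``, a uniform sample without
    replacement is taken (seeded, fixed once per run); kept neighbors are
    returned in graph node order so the context is deterministic.
    """
    if center not in graph.adjacency:
        raise KeyError(f"unknown node {center!r}")
    if max_neighbors < 1:
        raise ValueError("max_neighbors must be >= 1")
    order = graph.node_order()
    nbrs = sorted(graph.adjacency[center], key=order.__getitem__)
    full_degree = len(nbrs)
    if full_degree > max_neighbors:
        rng = np.random.default_rng(seed)
        keep = rng.choice(full_degree, size=max_neighbors, replace=False)
        nbrs = [nbrs[i] for i in sorted(keep)]
    dists = (
        emb.distances_from(center, nbrs) if nbrs else np.empty(0)
    )
    return NeighborContext(center, nbrs, dists, max_neighbors, full_degree)


def all_neighbor_contexts(
    graph: Graph,
    emb: EmbeddingMatrix,
    max_neighbors: int = 10,
    seed: int = 0,
) -> list[NeighborContext]:
    """Contexts for every node, with per-node derived sampling seeds."""
    return [
        neighbor_context(graph, emb, v, max_neighbors, seed=seed + i)
        for i, v in enumerate(graph.nodes)
    ]


def normalize_distance(d, mode: str = "N"):
    """Sigmoid-normalize a raw distance.

    Mode ``N``: d' = 1/(1+e^d), strictly decreasing in d (inverse
    relation: far neighbors get small d').  Mode ``F``: d' = 1/(1+e^-d),
    strictly increasing (proportional relation).  For every d,
    N(d) + F(d) = 1.
    """
    d = np.asarray(d, dtype=np.float64)
    if mode == "N":
        out = 1.0 / (1.0 + np.exp(d))
    elif mode == "F":
        out = 1.0 / (1.0 + np.exp(-d))
    else:
        raise ValueError(f"mode must be 'N' or 'F', got {mode!r}")
    return out if out.ndim else float(out)


def nonlearning_weights(ctx: NeighborContext, mode: str = "N") -> WeightVector:
    """Closed-form neighbor weights: softmax of e^{d'} over the context."""
    if not ctx.neighbors:
        raise ValueError(
            f"node {ctx.center!r} has no neighbors; use the degree-0 fallback"
        )
    d_norm = normalize_distance(ctx.distances, mode)
    z = np.exp(d_norm)
    return WeightVector(z / z.sum(), mode)


def select_weighting(
    ctx: NeighborContext,
    policy: str,
    model=None,
    degree_threshold: int = 10,
    emb: EmbeddingMatrix | None = None,
) -> WeightVector:
    """Dispatch a context to the weight calculator the policy prescribes.

    Pure policies route directly.  Hybrid policies (``1H+N``, ``MH+N``)
    use the attention model when ``full_degree <= degree_threshold`` and
    the non-learning mode N otherwise.  The returned vector's ``mode``
    tag records which calculator actually ran.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {POLICIES}")
    if policy in ("N", "F"):
        return nonlearning_weights(ctx, policy)

    attn_mode = policy.split("+")[0]  # "1H" or "MH"
    hybrid = policy.endswith("+N")
    if hybrid and ctx.full_degree > degree_threshold:
        return nonlearning_weights(ctx, "N")
    if model is None:
        raise ValueError(f"policy {policy!r} requires a trained attention model")
    if emb is None:
        raise ValueError(f"policy {policy!r} requires the embedding matrix")
    expected_heads = 1 if attn_mode == "1H" else None
    if expected_heads is not None and model.heads != 1:
        raise ValueError("policy 1H requires a one-head model")
    if attn_mode == "MH" and model.heads < 2:
        raise ValueError("policy MH requires a multi-head model")
    from .attention import attention_weights

    return attention_weights(model, ctx, emb)
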