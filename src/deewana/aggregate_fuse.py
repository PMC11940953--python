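"""Neighborhood aggregation and PCA fusion of self + local vectors.

A node's *local representational vector* r'_u is a convex combination of
its neighbors' self-representational vectors: the unweighted mean
r'_u = (1/|n(u)|) sum_v r_v, or the weighted form r'_u = sum_v a_uv r_v
with a weight vector from the weighting/attention stage.  Self and local
vectors are then concatenated (self first) into a 2*d_model-wide matrix
and projected back to a single unified space by PCA.

Centering only, no variance scaling: both halves live on comparable
embedding scales, and scaling would distort their relative contribution.
Component signs follow a canonical rule (largest-|loading| coordinate is
positive), which makes the projection bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .embedding import EmbeddingMatrix
from .weighting import NeighborContext, WeightVector

__all__ = [
    "FusedEmbedding",
    "mean_aggregate",
    "weighted_aggregate",
    "build_local_table",
    "concat_representations",
    "pca_fuse",
]

logger = logging.getLogger(__name__)


@dataclass
class FusedEmbedding:
    """Fused node vectors plus the fitted projection (kept for audit)."""

    nodes: list[str]
    matrix: np.ndarray
    components: np.ndarray  # (out_dim, input_dim), orthonormal rows
    means: np.ndarray  # column means removed before projection

    @property
    def out_dim(self) -> int:
        return self.matrix.shape[1]

    def to_embedding(self) -> EmbeddingMatrix:
        return EmbeddingMatrix(list(self.nodes), self.matrix)


def mean_aggregate(ctx: NeighborContext, emb: EmbeddingMatrix) -> np.ndarray:
    """Unweighted mean of the neighbors' self-vectors.

    Degree-0 fallback: an isolated node has no neighborhood to average,
    so its local vector is its own self-vector (logged).
    """
    if not ctx.neighbors:
        logger.warning("node %r is isolated; local vector = self vector", ctx.center)
        return emb.row(ctx.center).copy()
    return emb.rows(ctx.neighbors).mean(axis=0)


def weighted_aggregate(
    ctx: NeighborContext, weights: WeightVector, emb: EmbeddingMatrix
) -> np.ndarray:
    """Weighted neighborhood aggregation: sum_v a_uv * r_v."""
    if len(weights) != len(ctx.neighbors):
        raise ValueError(
            f"{len(weights)} weights for {len(ctx.neighbors)} neighbors"
        )
    if not np.isclose(weights.weights.sum(), 1.0, atol=1e-6):
        raise ValueError("weights do not sum to 1")
    return weights.weights @ emb.rows(ctx.neighbors)


def build_local_table(
    contexts: list[NeighborContext],
    weight_vectors: dict[str, WeightVector | None],
    emb: EmbeddingMatrix,
) -> EmbeddingMatrix:
    """Local vectors for every context, as an embedding-like matrix.

    ``weight_vectors`` maps center node -> WeightVector, or None for the
    unweighted mean.  Isolated nodes take the identity fallback.
    """
    nodes, rows = [], []
    for ctx in contexts:
        w = weight_vectors.get(ctx.center)
        if not ctx.neighbors or w is None:
            rows.append(mean_aggregate(ctx, emb))
        else:
            rows.append(weighted_aggregate(ctx, w, emb))
        nodes.append(ctx.center)
    return EmbeddingMatrix(nodes, np.vstack(rows))


def concat_representations(
    self_emb: EmbeddingMatrix, local: EmbeddingMatrix
) -> tuple[list[str], np.ndarray]:
    """Concatenate self then local vectors per node (width 2*d_model)."""
    missing = set(self_emb.nodes) ^ set(local.nodes)
    if missing:
        raise ValueError(f"node sets differ; symmetric difference: {sorted(missing)}")
    nodes = list(self_emb.nodes)
    mat = np.hstack([self_emb.matrix, local.rows(nodes)])
    return nodes, mat


def pca_fuse(
    nodes: list[str], concat: np.ndarray, out_dim: int = 128
) -> FusedEmbedding:
    """Project the concatenated representation onto its top principal axes.

    Columns are centered (not scaled); the projection keeps ``out_dim``
    components with the canonical sign rule.  Requires more rows than
    components so the covariance has enough rank headroom.
    """
    n, d2 = concat.shape
    if out_dim < 1:
        raise ValueError("out_dim must be >= 1")
    if out_dim > min(n - 1, d2):
        raise ValueError(
            f"out_dim={out_dim} exceeds min(n_rows-1, n_cols)={min(n - 1, d2)}"
        )
    means = concat.mean(axis=0)
    xc = concat - means
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    components = vt[:out_dim]
    # canonical signs: largest-|loading| entry of each component positive
    flip = components[np.arange(out_dim), np.abs(components).argmax(axis=1)] < 0
    components[flip] *= -1.0
    scores = xc @ components.T
    return FusedEmbedding(list(nodes), scores, components, means)
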