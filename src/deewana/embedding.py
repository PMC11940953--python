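"""Node-embedding container shared by every stage of the pipeline.

An :class:`EmbeddingMatrix` maps each node of a graph to a ``d_model``-
dimensional real vector (the node's *self-representational vector*).  Row
order follows the graph's node order so the same index can be reused for
every matrix built downstream (local vectors, concatenation, PCA scores).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EmbeddingMatrix"]


@dataclass
class EmbeddingMatrix:
    """Dense node -> vector map with a stable row order.

    Parameters
    ----------
    nodes
        Node identifiers, one per row, in the order rows appear in
        ``matrix``.
    matrix
        Array of shape ``(len(nodes), d_model)``; all entries finite.
    """

    nodes: list[str]
    matrix: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("embedding matrix must be 2-D")
        if len(self.nodes) != self.matrix.shape[0]:
            raise ValueError(
                f"{len(self.nodes)} nodes but {self.matrix.shape[0]} matrix rows"
            )
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node identifiers in embedding")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite entries in embedding matrix")
        self._index = {v: i for i, v in enumerate(self.nodes)}

    @property
    def d_model(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def row(self, node: str) -> np.ndarray:
        """Vector of a single node (view into the matrix)."""
        return self.matrix[self._index[node]]

    def rows(self, nodes) -> np.ndarray:
        """Stacked vectors for an iterable of nodes."""
        idx = [self._index[v] for v in nodes]
        return self.matrix[idx]

    def index_of(self, node: str) -> int:
        return self._index[node]

    def distances_from(self, center: str, nodes) -> np.ndarray:
        """Euclidean distances ``||r_center - r_v||_2`` for each v."""
        diff = self.rows(nodes) - self.row(center)
        return np.linalg.norm(diff, axis=1)
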