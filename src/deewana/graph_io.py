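"""Graphs, label tables, text I/O and synthetic community-graph generators.

The method operates on simple undirected graphs.  Node identifiers are
opaque strings: integer-looking ids are never coerced, which avoids silent
re-indexing when real edge lists mix conventions.  Node order is the order
of first appearance and is reused everywhere a matrix row index is needed.

Synthetic generators produce the community-structured graphs the method
assumes: a planted-partition (stochastic block model) graph for the
single-label case, and an overlapping-membership variant for the
multi-label case, where sharing at least one label raises the edge
probability from ``p_out`` to ``p_in``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .embedding import EmbeddingMatrix

__all__ = [
    "Graph",
    "LabelTable",
    "SyntheticSpec",
    "read_edgelist",
    "read_label_table",
    "read_embeddings",
    "write_embeddings",
    "generate_sbm_graph",
    "generate_multilabel_graph",
]

logger = logging.getLogger(__name__)


@dataclass
class Graph:
    """Simple undirected graph with deterministic node order.

    ``nodes`` lists identifiers in insertion order (first appearance);
    ``adjacency`` is symmetric and contains no self-loops.
    """

    nodes: list[str] = field(default_factory=list)
    adjacency: dict[str, set[str]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def add_node(self, v: str) -> None:
        if v not in self.adjacency:
            self.nodes.append(v)
            self.adjacency[v] = set()

    def add_edge(self, u: str, v: str) -> bool:
        """Add an undirected edge; returns False for self-loops/duplicates."""
        if u == v:
            return False
        self.add_node(u)
        self.add_node(v)
        if v in self.adjacency[u]:
            return False
        self.adjacency[u].add(v)
        self.adjacency[v].add(u)
        return True

    def neighbors(self, v: str) -> set[str]:
        return self.adjacency[v]

    def degree(self, v: str) -> int:
        return len(self.adjacency[v])

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self.adjacency.values()) // 2

    def node_order(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.nodes)}


@dataclass
class LabelTable:
    """Node -> non-empty set of label identifiers.

    ``multilabel`` is True iff any node carries two or more labels.
    Insertion order of nodes is preserved (used for deterministic splits).
    """

    labels: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v, labs in self.labels.items():
            if not labs:
                raise ValueError(f"node {v!r} has no labels")

    @property
    def multilabel(self) -> bool:
        return any(len(s) > 1 for s in self.labels.values())

    @property
    def label_universe(self) -> list[str]:
        seen: set[str] = set()
        for s in self.labels.values():
            seen |= s
        return sorted(seen)

    def nodes(self) -> list[str]:
        return list(self.labels.keys())

    def __getitem__(self, v: str) -> set[str]:
        return self.labels[v]

    def __contains__(self, v: str) -> bool:
        return v in self.labels

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic labeled-graph generators.

    ``p_in`` is the edge probability for node pairs in the same community
    (or sharing a label); ``p_out`` for all other pairs.  Community signal
    requires ``p_out < p_in``.
    """

    n_nodes: int
    n_blocks: int
    p_in: float
    p_out: float
    labels_per_node: tuple[int, int] = (1, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be positive")
        if self.n_blocks < 2:
            raise ValueError("need at least 2 blocks/labels")
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise ValueError(
                f"need 0 <= p_out <= p_in <= 1, got p_in={self.p_in}, p_out={self.p_out}"
            )
        lo, hi = self.labels_per_node
        if not (1 <= lo <= hi):
            raise ValueError("labels_per_node must be a range of positive ints")


class EdgelistParseError(ValueError):
    pass


def read_edgelist(path: str | Path) -> Graph:
    """Read a whitespace-delimited edge list into a :class:`Graph`.

    One edge per line (first two tokens are node ids); ``#`` starts a
    comment; blank lines are skipped.  Duplicate edges are collapsed and
    self-loops dropped, with counts logged and recorded in ``graph.meta``.
    """
    path = Path(path)
    g = Graph()
    self_loops = 0
    duplicates = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise EdgelistParseError(
                    f"{path}:{lineno}: expected at least 2 tokens, got {len(tokens)}"
                )
            u, v = tokens[0], tokens[1]
            if u == v:
                g.add_node(u)
                self_loops += 1
            elif not g.add_edge(u, v):
                duplicates += 1
    g.meta.update(self_loops_dropped=self_loops, duplicate_edges=duplicates)
    logger.info(
        "read %s: %d nodes, %d edges (%d self-loops dropped, %d duplicates)",
        path, g.n_nodes, g.n_edges, self_loops, duplicates,
    )
    return g


def read_label_table(path: str | Path, delimiter: str = ",") -> LabelTable:
    """Read a node-label table.

    Each line: a node id, whitespace, then one or more label tokens; each
    label token may itself pack several labels joined by ``delimiter``.
    Duplicate node lines have their label sets unioned (warned).
    """
    path = Path(path)
    labels: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise EdgelistParseError(
                    f"{path}:{lineno}: node {tokens[0]!r} has no labels"
                )
            node = tokens[0]
            labs = {
                lab
                for tok in tokens[1:]
                for lab in tok.split(delimiter)
                if lab
            }
            if not labs:
                raise EdgelistParseError(f"{path}:{lineno}: empty label set")
            if node in labels:
                logger.warning("%s:%d: duplicate node %r, labels unioned", path, lineno, node)
                labels[node] |= labs
            else:
                labels[node] = labs
    return LabelTable(labels)


def write_embeddings(emb: EmbeddingMatrix, path: str | Path) -> None:
    """Write embeddings in the standard whitespace text format.

    First line is ``"N d"``; each following line is ``id v1 ... vd`` at
    full float precision, so a write/read round trip is lossless.
    """
    if emb.n_nodes == 0:
        raise ValueError("refusing to write an empty embedding")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{emb.n_nodes} {emb.d_model}\n")
        for node, row in zip(emb.nodes, emb.matrix):
            vals = " ".join(format(x, ".17g") for x in row)
            fh.write(f"{node} {vals}\n")


def read_embeddings(path: str | Path) -> EmbeddingMatrix:
    """Read the ``"N d"``-headed whitespace embedding text format."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise EdgelistParseError(f"{path}:1: malformed header {header}")
        n, d = int(header[0]), int(header[1])
        nodes: list[str] = []
        rows = np.empty((n, d), dtype=np.float64)
        for i in range(n):
            tokens = fh.readline().split()
            if len(tokens) != d + 1:
                raise EdgelistParseError(
                    f"{path}:{i + 2}: expected {d + 1} tokens, got {len(tokens)}"
                )
            nodes.append(tokens[0])
            rows[i] = [float(t) for t in tokens[1:]]
    return EmbeddingMatrix(nodes, rows)


def _pairwise_edges(
    rng: np.random.Generator, n: int, prob_fn
) -> list[tuple[int, int]]:
    """Sample undirected edges over all i<j pairs with per-pair probability."""
    iu, ju = np.triu_indices(n, k=1)
    p = prob_fn(iu, ju)
    keep = rng.random(iu.shape[0]) < p
    return list(zip(iu[keep].tolist(), ju[keep].tolist()))


def _build_graph(n: int, edges: list[tuple[int, int]]) -> Graph:
    g = Graph()
    for i in range(n):
        g.add_node(f"v{i}")
    for i, j in edges:
        g.add_edge(f"v{i}", f"v{j}")
    return g


def generate_sbm_graph(spec: SyntheticSpec) -> tuple[Graph, LabelTable]:
    """Planted-partition graph with the block index as the single label.

    Nodes are split into ``n_blocks`` near-equal blocks; a within-block
    pair is an edge with probability ``p_in``, a cross-block pair with
    ``p_out``.  Bit-reproducible for a fixed seed.
    """
    if spec.p_in <= spec.p_out:
        raise ValueError("community signal absent: need p_in > p_out")
    rng = np.random.default_rng(spec.seed)
    n, b = spec.n_nodes, spec.n_blocks
    sizes = [n // b + (1 if i < n % b else 0) for i in range(b)]
    block = np.repeat(np.arange(b), sizes)

    edges = _pairwise_edges(
        rng, n,
        lambda iu, ju: np.where(block[iu] == block[ju], spec.p_in, spec.p_out),
    )
    g = _build_graph(n, edges)
    g.meta.update(generator="sbm", spec=spec)
    labels = LabelTable({f"v{i}": {f"c{block[i]}"} for i in range(n)})
    return g, labels


def generate_multilabel_graph(spec: SyntheticSpec) -> tuple[Graph, LabelTable]:
    """Overlapping-membership community graph for the multi-label case.

    Each node draws its label count k uniformly from ``labels_per_node``,
    then k distinct labels uniformly from ``n_blocks`` labels.  A pair
    sharing at least one label is an edge with probability ``p_in``,
    otherwise ``p_out``.  Every label is used by at least one node.
    """
    lo, hi = spec.labels_per_node
    if spec.n_blocks < hi:
        raise ValueError(
            f"n_blocks={spec.n_blocks} < max labels_per_node={hi}"
        )
    rng = np.random.default_rng(spec.seed)
    n, n_labels = spec.n_nodes, spec.n_blocks

    # resample until every label is used (near-certain on the first draw
    # at realistic sizes; the loop keeps the guarantee deterministic)
    for _ in range(100):
        counts = rng.integers(lo, hi + 1, size=n)
        membership = np.zeros((n, n_labels), dtype=bool)
        for i in range(n):
            chosen = rng.choice(n_labels, size=counts[i], replace=False)
            membership[i, chosen] = True
        if membership.any(axis=0).all():
            break
    else:
        raise RuntimeError("could not cover every label; increase n_nodes")

    share = (membership @ membership.T) > 0  # pair shares >=1 label
    edges = _pairwise_edges(
        rng, n,
        lambda iu, ju: np.where(share[iu, ju], spec.p_in, spec.p_out),
    )
    g = _build_graph(n, edges)
    g.meta.update(generator="multilabel", spec=spec)
    labels = LabelTable(
        {
            f"v{i}": {f"c{j}" for j in np.flatnonzero(membership[i])}
            for i in range(n)
        }
    )
    return g, labels
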