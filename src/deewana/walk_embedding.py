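"""Self-representational vectors from truncated random walks + skip-gram.

This is the first stage of the pipeline: uniform random walks sample node
sequences from the graph, and a skip-gram model with negative sampling is
trained on those sequences, exactly as in DeepWalk.  The resulting vector
r_v for node v is its *self-representational vector*; every later stage
(distance computation, neighbor weighting, aggregation, fusion) consumes
these vectors and never feeds back into them.

The trainer is a plain numpy implementation of skip-gram with negative
sampling: dynamic context windows (a pair at offset k is kept with
probability (window-k+1)/window, the classic equivalent of drawing a
window size uniformly from 1..window), 5 negatives per positive drawn
from the unigram^0.75 distribution, and a linearly decaying learning
rate.  It runs single-threaded and is bit-reproducible for a fixed seed.
Any compliant trainer can be substituted: the contract is only
"walk corpus in, one finite d_model vector per node out".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .embedding import EmbeddingMatrix
from .graph_io import Graph

__all__ = ["WalkCorpus", "simulate_walks", "train_skipgram"]


@dataclass
class WalkCorpus:
    """Random-walk corpus: node sequences plus the node universe.

    Every consecutive pair in every walk is an edge of the source graph;
    every node starts exactly ``walks_per_node`` walks (isolated nodes
    yield length-1 walks).
    """

    walks: list[list[str]]
    nodes: list[str]
    walks_per_node: int
    walk_length: int

    def __len__(self) -> int:
        return len(self.walks)


def simulate_walks(
    graph: Graph,
    walks_per_node: int = 80,
    walk_length: int = 40,
    seed: int = 0,
) -> WalkCorpus:
    """Sample truncated uniform random walks from every node.

    For each of ``walks_per_node`` passes the start-node order is shuffled
    (same generator), and from each start node a walk of at most
    ``walk_length`` nodes is taken, moving to a uniformly random neighbor
    at each step.  A walk stops early only at a degree-0 node.
    """
    if graph.n_nodes == 0:
        raise ValueError("graph is empty")
    if walk_length < 1:
        raise ValueError("walk_length must be >= 1")
    if walks_per_node < 1:
        raise ValueError("walks_per_node must be >= 1")

    rng = np.random.default_rng(seed)
    order = graph.node_order()
    names = graph.nodes
    # neighbor lists in node order, as int indices, for fast stepping
    nbrs = [
        np.array(sorted((order[u] for u in graph.adjacency[v])), dtype=np.int64)
        for v in names
    ]
    degs = np.array([len(a) for a in nbrs])

    walks: list[list[str]] = []
    n = graph.n_nodes
    for _ in range(walks_per_node):
        starts = rng.permutation(n)
        for s in starts:
            if degs[s] == 0:
                walks.append([names[s]])
                continue
            # one RNG draw per walk: uniform deviates turned into
            # neighbor indices on the fly
            u = rng.random(walk_length - 1)
            walk = [int(s)]
            cur = int(s)
            for t in range(walk_length - 1):
                d = degs[cur]
                if d == 0:
                    break
                cur = int(nbrs[cur][int(u[t] * d)])
                walk.append(cur)
            walks.append([names[i] for i in walk])
    return WalkCorpus(walks, list(names), walks_per_node, walk_length)


def _pair_arrays(
    walks_idx: list[np.ndarray], window: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten walks and precompute all (center, context, offset) triples.

    Offsets are needed to apply the dynamic-window keep probability
    per epoch without rebuilding the pair list.
    """
    tokens = np.concatenate(walks_idx)
    lengths = np.array([len(w) for w in walks_idx])
    walk_id = np.repeat(np.arange(len(walks_idx)), lengths)

    centers, contexts, offsets = [], [], []
    for k in range(1, window + 1):
        if len(tokens) <= k:
            break
        same = walk_id[:-k] == walk_id[k:]
        a = tokens[:-k][same]
        b = tokens[k:][same]
        # both directions: (a predicts b) and (b predicts a)
        centers.append(a)
        contexts.append(b)
        centers.append(b)
        contexts.append(a)
        offsets.append(np.full(2 * a.shape[0], k, dtype=np.int64))
    return (
        np.concatenate(centers),
        np.concatenate(contexts),
        np.concatenate(offsets),
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def _scatter_add(w: np.ndarray, idx: np.ndarray, grad: np.ndarray) -> None:
    """w[idx] += grad with repeated indices accumulated.

    Done as a sparse one-hot matmul, which is much faster than np.add.at
    for the many-repeats/small-vocabulary case of node corpora.
    """
    m = idx.shape[0]
    onehot = sp.csr_matrix(
        (np.ones(m, dtype=grad.dtype), (idx, np.arange(m))), shape=(w.shape[0], m)
    )
    w += onehot @ grad


def train_skipgram(
    corpus: WalkCorpus,
    d_model: int = 128,
    window: int = 10,
    epochs: int = 5,
    seed: int = 0,
    negative: int = 5,
    alpha: float = 0.025,
    min_alpha: float = 1e-4,
    batch_size: int = 8192,
) -> EmbeddingMatrix:
    """Train skip-gram with negative sampling on a walk corpus.

    Returns an :class:`EmbeddingMatrix` with one ``d_model``-dimensional
    row per corpus node, rows ordered as ``corpus.nodes``.  Raises if any
    node of the corpus universe never appears in a walk (which would
    otherwise leave an untrained row silently).
    """
    if not corpus.walks:
        raise ValueError("corpus is empty")
    index = {v: i for i, v in enumerate(corpus.nodes)}
    n_vocab = len(corpus.nodes)

    walks_idx = [
        np.array([index[v] for v in walk], dtype=np.int64)
        for walk in corpus.walks
    ]
    freq = np.bincount(np.concatenate(walks_idx), minlength=n_vocab)
    missing = np.flatnonzero(freq == 0)
    if missing.size:
        raise ValueError(
            f"node {corpus.nodes[int(missing[0])]!r} never appears in the corpus"
        )

    rng = np.random.default_rng(seed)
    # float32 throughout the update loop: the model is stochastic at 1e-7
    # scale anyway and the halved memory traffic roughly doubles throughput
    w_in = ((rng.random((n_vocab, d_model)) - 0.5) / d_model).astype(np.float32)
    w_out = np.zeros((n_vocab, d_model), dtype=np.float32)

    # unigram^0.75 negative-sampling distribution
    noise = freq.astype(np.float64) ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    centers, contexts, offsets = _pair_arrays(walks_idx, window)
    keep_p = (window - offsets + 1) / window
    total_pairs_est = max(1, int(keep_p.sum()) * epochs)

    # within a mini-batch every repeat of a row contributes a gradient
    # evaluated at the same (stale) value, so the batch must stay small
    # relative to the vocabulary or updates compound into divergence
    batch_size = int(min(batch_size, max(64, 4 * n_vocab)))

    processed = 0
    for _ in range(epochs):
        keep = rng.random(centers.shape[0]) < keep_p
        c_ep = centers[keep]
        o_ep = contexts[keep]
        perm = rng.permutation(c_ep.shape[0])
        c_ep, o_ep = c_ep[perm], o_ep[perm]

        for start in range(0, c_ep.shape[0], batch_size):
            c = c_ep[start:start + batch_size]
            o = o_ep[start:start + batch_size]
            b = c.shape[0]
            neg = np.searchsorted(noise_cdf, rng.random((b, negative)))

            lr = np.float32(max(min_alpha, alpha * (1.0 - processed / total_pairs_est)))
            vc = w_in[c]  # (b, d) snapshot
            vo = w_out[o]
            vn = w_out[neg]  # (b, k, d)

            g_pos = _sigmoid(np.einsum("bd,bd->b", vc, vo)) - 1.0  # (b,)
            g_neg = _sigmoid(np.einsum("bd,bkd->bk", vc, vn))  # (b, k)

            grad_c = g_pos[:, None] * vo + np.einsum("bk,bkd->bd", g_neg, vn)
            _scatter_add(w_in, c, -lr * grad_c)
            out_idx = np.concatenate([o, neg.ravel()])
            out_grad = np.concatenate(
                [
                    -lr * g_pos[:, None] * vc,
                    (-lr * g_neg[..., None] * vc[:, None, :]).reshape(-1, d_model),
                ]
            )
            _scatter_add(w_out, out_idx, out_grad)
            processed += b

    return EmbeddingMatrix(list(corpus.nodes), w_in.astype(np.float64))
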