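"""Shared fixtures: small synthetic graphs and embeddings, built at test time."""

from __future__ import annotations

import numpy as np
import pytest

import deewana as dw


@pytest.fixture(scope="session")
def clique_graph():
    """Three disjoint 10-cliques with the clique index as label."""
    return dw.generate_sbm_graph(dw.SyntheticSpec(30, 3, 1.0, 0.0, seed=1))


@pytest.fixture(scope="session")
def sbm_graph():
    """Sparse 3-block planted partition, the community fixture used widely."""
    return dw.generate_sbm_graph(dw.SyntheticSpec(90, 3, 0.3, 0.02, seed=7))


@pytest.fixture(scope="session")
def clique_embedding(clique_graph):
    """Walk + skip-gram embedding of the clique graph (small dims for speed)."""
    graph, _ = clique_graph
    corpus = dw.simulate_walks(graph, walks_per_node=10, walk_length=20, seed=1)
    return dw.train_skipgram(corpus, d_model=32, window=5, epochs=3, seed=1)


@pytest.fixture(scope="session")
def sbm_embedding(sbm_graph):
    graph, _ = sbm_graph
    corpus = dw.simulate_walks(graph, walks_per_node=10, walk_length=20, seed=7)
    return dw.train_skipgram(corpus, d_model=32, window=5, epochs=3, seed=7)


@pytest.fixture()
def random_embedding():
    """Factory for random embeddings over a synthetic node universe."""

    def make(n_nodes: int, d: int, seed: int = 0) -> dw.EmbeddingMatrix:
        rng = np.random.default_rng(seed)
        return dw.EmbeddingMatrix(
            [f"v{i}" for i in range(n_nodes)], rng.normal(size=(n_nodes, d))
        )

    return make


def make_context(distances, center="u", max_neighbors=10, full_degree=None):
    """NeighborContext straight from a distance list (no graph needed)."""
    distances = np.asarray(distances, dtype=float)
    k = distances.shape[0]
    return dw.NeighborContext(
        center=center,
        neighbors=[f"nb{i}" for i in range(k)],
        distances=distances,
        max_neighbors=max_neighbors,
        full_degree=k if full_degree is None else full_degree,
    )
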