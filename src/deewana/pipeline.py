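"""End-to-end orchestration: embed -> weight -> aggregate -> fuse -> evaluate.

The stages are strictly feed-forward: the self-representational embedding
is computed once and frozen; distances, weights, local vectors and the
fused space are all derived from it.  ``run_pipeline`` drives the whole
chain from files on disk and caches the expensive embedding stage keyed
by a hash of the embedding-relevant configuration, so ablations that only
change downstream choices (weighting policy, fusion mode) reuse it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .aggregate_fuse import build_local_table, concat_representations, pca_fuse
from .attention import build_attention_model, train_attention
from .embedding import EmbeddingMatrix
from .evaluate import EvalConfig, EvalResult, evaluate_protocol
from .graph_io import (
    Graph,
    LabelTable,
    SyntheticSpec,
    generate_multilabel_graph,
    generate_sbm_graph,
    read_edgelist,
    read_embeddings,
    read_label_table,
    write_embeddings,
)
from .walk_embedding import simulate_walks, train_skipgram
from .weighting import POLICIES, all_neighbor_contexts, select_weighting

__all__ = [
    "PipelineConfig",
    "embed_graph",
    "build_representation",
    "run_pipeline",
    "make_fixture",
]

logger = logging.getLogger(__name__)

FUSION_MODES = ("pca", "cnt", "local", "self")


@dataclass
class PipelineConfig:
    """Everything that determines a run; serialized next to the outputs."""

    edgelist: str | None = None
    labels: str | None = None
    embedding_file: str | None = None  # skip the walk stage, inject vectors
    outdir: str = "deewana_out"

    # walk + skip-gram stage
    dim: int = 128
    walks_per_node: int = 80
    walk_length: int = 40
    window: int = 10
    epochs: int = 5

    # weighting stage
    weighting: str = "N"
    max_neighbors: int = 10
    degree_threshold: int = 10
    heads: int = 4
    attention_epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 32

    # fusion stage
    fusion: str = "pca"
    out_dim: int = 128

    # evaluation stage
    proportions: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weighting not in POLICIES:
            raise ValueError(f"weighting must be one of {POLICIES}")
        if self.fusion not in FUSION_MODES:
            raise ValueError(f"fusion must be one of {FUSION_MODES}")

    def embed_key(self) -> str:
        """Hash of the fields that determine the self-embedding."""
        payload = json.dumps(
            [
                self.edgelist, self.embedding_file, self.dim,
                self.walks_per_node, self.walk_length, self.window,
                self.epochs, self.seed,
            ]
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def embed_graph(graph: Graph, cfg: PipelineConfig) -> EmbeddingMatrix:
    """Walk + skip-gram stage producing the self-representational vectors."""
    corpus = simulate_walks(
        graph, cfg.walks_per_node, cfg.walk_length, seed=cfg.seed
    )
    return train_skipgram(
        corpus, d_model=cfg.dim, window=cfg.window, epochs=cfg.epochs,
        seed=cfg.seed,
    )


def _needs_attention(policy: str) -> bool:
    return policy not in ("N", "F")


def build_representation(
    graph: Graph, emb: EmbeddingMatrix, cfg: PipelineConfig
):
    """Weight, aggregate and fuse; returns (final embedding, local table, model).

    ``cfg.fusion`` selects the final representation: ``pca`` (the full
    method), ``cnt`` (unfused 2*dim concatenation), ``local`` (local
    vectors only) or ``self`` (the walk embedding unchanged, i.e. the
    baseline).
    """
    if cfg.fusion == "self":
        return emb, None, None

    contexts = all_neighbor_contexts(
        graph, emb, max_neighbors=cfg.max_neighbors, seed=cfg.seed
    )
    model = None
    if _needs_attention(cfg.weighting):
        heads = 1 if cfg.weighting.startswith("1H") else cfg.heads
        model = build_attention_model(
            d_model=emb.d_model, heads=heads,
            max_neighbors=cfg.max_neighbors, seed=cfg.seed,
        )
        trainable = [c for c in contexts if c.neighbors]
        model, history = train_attention(
            model, trainable, emb,
            epochs=cfg.attention_epochs, learning_rate=cfg.learning_rate,
            batch_size=cfg.batch_size, seed=cfg.seed,
        )
        if history:
            logger.info(
                "attention training loss: %.4g -> %.4g", history[0], history[-1]
            )

    weight_vectors = {
        ctx.center: (
            select_weighting(
                ctx, cfg.weighting, model=model,
                degree_threshold=cfg.degree_threshold, emb=emb,
            )
            if ctx.neighbors
            else None
        )
        for ctx in contexts
    }
    local = build_local_table(contexts, weight_vectors, emb)

    if cfg.fusion == "local":
        return local, local, model
    nodes, concat = concat_representations(emb, local)
    if cfg.fusion == "cnt":
        return EmbeddingMatrix(nodes, concat), local, model
    fused = pca_fuse(nodes, concat, out_dim=cfg.out_dim)
    return fused.to_embedding(), local, model


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full pipeline from files and write all artifacts to disk.

    Returns a dict with the final embedding, the :class:`EvalResult` and
    the paths written.  Rerunning with an identical config reproduces
    identical tables.
    """
    if cfg.edgelist is None or cfg.labels is None:
        raise ValueError("edgelist and labels paths are required")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    graph = read_edgelist(cfg.edgelist)
    labels = read_label_table(cfg.labels)
    unknown = [v for v in labels.nodes() if v not in graph.adjacency]
    if unknown:
        raise ValueError(f"labeled nodes absent from graph: {unknown[:5]}")

    # stage 1: self-representational vectors (cached by config hash)
    cache = outdir / f"selfemb_{cfg.embed_key()}.emb"
    if cfg.embedding_file:
        emb = read_embeddings(cfg.embedding_file)
    elif cache.exists():
        logger.info("reusing cached embedding %s", cache)
        emb = read_embeddings(cache)
    else:
        emb = embed_graph(graph, cfg)
        write_embeddings(emb, cache)

    # stages 2-4: weights, aggregation, fusion
    final, local, model = build_representation(graph, emb, cfg)
    final_path = outdir / "final_embedding.emb"
    write_embeddings(final, final_path)

    # stage 5: node-classification protocol on labeled nodes only
    eval_cfg = EvalConfig(
        proportions=cfg.proportions, repeats=cfg.repeats, base_seed=cfg.seed
    )
    result = evaluate_protocol(final, labels, eval_cfg)
    scores_path = outdir / "scores.csv"
    summary_path = outdir / "summary.csv"
    result.scores.to_csv(scores_path, index=False)
    result.summary.to_csv(summary_path, index=False)

    config_path = outdir / "config.json"
    config_path.write_text(json.dumps(dataclasses.asdict(cfg), indent=2))

    return dict(
        graph=graph,
        labels=labels,
        self_embedding=emb,
        final_embedding=final,
        result=result,
        paths=dict(
            self_embedding=cache,
            final_embedding=final_path,
            scores=scores_path,
            summary=summary_path,
            config=config_path,
        ),
    )


def make_fixture(
    kind: str, spec: SyntheticSpec, outdir: str | Path
) -> tuple[Path, Path]:
    """Write a synthetic labeled graph as edge-list + label files.

    ``kind`` is ``"single"`` (planted partition) or ``"multi"``
    (overlapping memberships, comma-joined labels).  Byte-identical for a
    fixed spec.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "single":
        graph, labels = generate_sbm_graph(spec)
    elif kind == "multi":
        graph, labels = generate_multilabel_graph(spec)
    else:
        raise ValueError("kind must be 'single' or 'multi'")

    edge_path = outdir / f"{kind}_edges.txt"
    label_path = outdir / f"{kind}_labels.txt"
    with open(edge_path, "w") as fh:
        order = graph.node_order()
        for u in graph.nodes:
            for v in sorted(graph.adjacency[u], key=order.__getitem__):
                if order[u] < order[v]:
                    fh.write(f"{u} {v}\n")
    with open(label_path, "w") as fh:
        for v in labels.nodes():
            fh.write(f"{v} {','.join(sorted(labels[v]))}\n")
    (outdir / f"{kind}_spec.json").write_text(
        json.dumps(dataclasses.asdict(spec), indent=2)
    )
    return edge_path, label_path
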