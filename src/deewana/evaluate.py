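"""Node-classification evaluation: repeated splits, one-vs-rest, Micro-F1.

The standard protocol for judging unsupervised node embeddings: a
proportion of the labeled nodes is drawn at random as the training set, a
one-vs-rest L2-regularized logistic regression is fitted per label on the
embedding rows, and predictions on the held-out nodes are scored by
micro-averaged F1, pooling label decisions across all nodes.  The split /
fit / score cycle is repeated (default 10 times) at each training
proportion (default 0.2, 0.4, 0.6, 0.8) and means are reported.

Multi-label convention: each test node receives its top-k_i scored
labels, where k_i is that node's true label count.  This "known label
count" rule is the convention of the classic embedding-evaluation
protocol; Micro-F1 numbers are not comparable across papers without it.
In the single-label case top-1 prediction makes Micro-F1 equal accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .embedding import EmbeddingMatrix
from .graph_io import LabelTable

__all__ = [
    "EvalConfig",
    "EvalResult",
    "split_nodes",
    "fit_predict_ovr",
    "micro_f1",
    "evaluate_protocol",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalConfig:
    """Grid of training proportions x repeats, with a base seed.

    Repeat r uses seed ``base_seed + r`` so repeats are independent but
    the whole grid is reproducible.
    """

    proportions: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    repeats: int = 10
    base_seed: int = 0
    classifier_c: float = 1.0  # inverse L2 strength of the per-label classifier

    def __post_init__(self) -> None:
        if not all(0.0 < p < 1.0 for p in self.proportions):
            raise ValueError("proportions must lie strictly in (0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class EvalResult:
    """Per-(proportion, repeat) Micro-F1 grid with summary statistics."""

    scores: pd.DataFrame  # columns: proportion, repeat, micro_f1

    summary: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.summary = (
            self.scores.groupby("proportion")["micro_f1"]
            .agg(["mean", "std"])
            .reset_index()
        )

    def mean(self, proportion: float) -> float:
        sel = self.summary[np.isclose(self.summary["proportion"], proportion)]
        return float(sel["mean"].iloc[0])


def split_nodes(
    labels: LabelTable, proportion: float, seed: int
) -> tuple[set[str], set[str]]:
    """Random train/test partition of the labeled nodes.

    ``|train| = round(proportion * N)``; unlabeled nodes never enter
    either side.  Unstratified, as in the protocol being reproduced.
    """
    if not (0.0 < proportion < 1.0):
        raise ValueError("proportion must be in (0, 1)")
    nodes = labels.nodes()
    if len(nodes) < 2:
        raise ValueError("need at least 2 labeled nodes")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(nodes))
    n_train = int(proportion * len(nodes) + 0.5)
    n_train = min(max(n_train, 1), len(nodes) - 1)
    train = {nodes[i] for i in perm[:n_train]}
    test = {nodes[i] for i in perm[n_train:]}
    return train, test


def fit_predict_ovr(
    emb: EmbeddingMatrix,
    labels: LabelTable,
    train: set[str],
    test: set[str],
    c: float = 1.0,
) -> dict[str, set[str]]:
    """One-vs-rest logistic regression; returns predicted label sets.

    Single-label data: arg-max label per test node.  Multi-label data:
    top-k_i labels with k_i the node's true label count.  Labels without
    both a positive and a negative training example are skipped (warned)
    and can never be predicted.
    """
    train_nodes = sorted(train)
    test_nodes = sorted(test)
    x_train = emb.rows(train_nodes)
    x_test = emb.rows(test_nodes)
    universe = labels.label_universe

    scores = np.full((len(test_nodes), len(universe)), -np.inf)
    for j, lab in enumerate(universe):
        y = np.array([lab in labels[v] for v in train_nodes])
        if y.all() or not y.any():
            logger.warning("label %r has a one-class training set; skipped", lab)
            continue
        clf = LogisticRegression(C=c, max_iter=1000)
        clf.fit(x_train, y)
        scores[:, j] = clf.decision_function(x_test)

    multilabel = labels.multilabel
    predicted: dict[str, set[str]] = {}
    for i, v in enumerate(test_nodes):
        if multilabel:
            k = len(labels[v])
            top = np.argsort(scores[i])[::-1][:k]
        else:
            top = [int(np.argmax(scores[i]))]
        predicted[v] = {universe[j] for j in top}
    return predicted


def micro_f1(predicted: dict[str, set[str]], truth: dict[str, set[str]]) -> float:
    """Micro-averaged F1 = 2TP / (2TP + FP + FN), pooled over all decisions."""
    if not truth:
        raise ValueError("empty test set")
    if set(predicted) != set(truth):
        raise ValueError("predicted and truth cover different nodes")
    tp = fp = fn = 0
    for v, true_set in truth.items():
        pred_set = predicted[v]
        tp += len(pred_set & true_set)
        fp += len(pred_set - true_set)
        fn += len(true_set - pred_set)
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def evaluate_protocol(
    emb: EmbeddingMatrix, labels: LabelTable, cfg: EvalConfig = EvalConfig()
) -> EvalResult:
    """Run the full split/fit/score grid and summarize.

    Deterministic for a fixed ``cfg.base_seed``: repeat r at every
    proportion splits with seed ``base_seed + r``.
    """
    missing = [v for v in labels.nodes() if v not in emb]
    if missing:
        raise ValueError(f"embedding missing labeled nodes: {missing[:5]}")
    records = []
    for prop in cfg.proportions:
        for r in range(cfg.repeats):
            train, test = split_nodes(labels, prop, cfg.base_seed + r)
            pred = fit_predict_ovr(emb, labels, train, test, c=cfg.classifier_c)
            truth = {v: labels[v] for v in test}
            records.append(
                dict(proportion=prop, repeat=r, micro_f1=micro_f1(pred, truth))
            )
    return EvalResult(pd.DataFrame.from_records(records))
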