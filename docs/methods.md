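# Methods

## The model

`deewana` learns unsupervised node representations for simple undirected
graphs G = (V, E) in four feed-forward stages.

**1. Self-representational vectors.** Truncated uniform random walks are
sampled from every node (`walks_per_node` walks of length `walk_length`
each, next step uniform over the current node's neighbors) and a skip-gram
model with negative sampling is trained on the walk corpus. The resulting
vector r_v ∈ R^d_model is node v's *self-representational* vector. This
stage is frozen once computed: nothing downstream feeds back into it.

**2. Neighbor weighting from embedding-space distances.** For each node u,
a one-hop neighbor context n(u) is formed (at most `max_neighbors`
neighbors, a seeded uniform sample without replacement if the degree is
larger) together with the Euclidean distances d_uv = ‖r_u − r_v‖₂.
Aggregation weights α_uv over the context come from one of two families:

* *Non-learning* (modes **N** and **F**): each distance is squashed by a
  sigmoid, d′ = 1/(1+e^d) for mode N (closer ⇒ larger d′ ⇒ larger
  weight) or d′ = 1/(1+e^{−d}) for mode F (the proportional variant), and
  the weights are w_uv = e^{d′_uv} / Σ_j e^{d′_uj}. Note that the mode-N
  map sends d ≥ 0 into (0, 0.5]; the formula is applied exactly in that
  form. The two modes are complementary (N(d) + F(d) = 1 pointwise).
* *Self-attention* (modes **1H** and **MH**): a scaled dot-product
  self-attention over the matrix I = [r_u; r_v1; …; r_vm] (zero-padded to
  n = 1 + `max_neighbors` rows), per head α = softmax(QKᵀ/√d_k) with
  Q = I·W_Q, K = I·W_K, V = I·W_V and d_k = d_v = d_model/h. The
  attention output, flattened, feeds a three-layer MLP with
  (n·d_model, n·d_model/2, n−1) neurons that predicts the n−1
  center–neighbor distances; training minimizes the squared error
  (d′ − d)² against the true embedding-space distances — an unsupervised,
  geometry-aware signal that needs no labels. The aggregation weights are
  read from the attention map itself: the center row restricted to
  real-neighbor columns, renormalized; for h heads, the mean of the
  per-head rows.

  Hybrid policies (**1H+N**, **MH+N**) use attention when the full degree
  is at most `degree_threshold` and the cheap closed form (mode N)
  otherwise, which is how the method scales to hub-heavy graphs.

**3. Aggregation and fusion.** The *local representational vector* is the
convex combination r′_u = Σ_v α_uv r_v (or the unweighted mean
r′_u = (1/|n(u)|) Σ_v r_v). Self and local vectors are concatenated —
self first — into a 2·d_model-wide matrix and projected back to `out_dim`
dimensions by PCA, giving the final unified representation.

**4. Evaluation.** Embedding quality is measured by the standard
node-classification protocol: a random proportion of labeled nodes trains
a one-vs-rest L2 logistic regression per label; held-out nodes are scored
by micro-averaged F1; the cycle repeats (default 10×) at each training
proportion (default 0.2/0.4/0.6/0.8) and means are reported. Multi-label
prediction uses the known-label-count convention: a test node with k true
labels receives its top-k scored labels. Under top-1 single-label
prediction, Micro-F1 equals accuracy.

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| `dim` (d_model) | 128 | representation width; all variants compared at the same width |
| `walks_per_node` | 80 | walk passes per node; with `walk_length` controls corpus size |
| `walk_length` | 40 | truncation length of each walk |
| `window` | 10 | skip-gram context radius (dynamic windows, word2vec convention) |
| `epochs` | 5 | skip-gram passes over the pair stream |
| `max_neighbors` | 10 | neighbor-context cap; larger contexts are uniformly subsampled |
| `heads` | 4 | multi-head attention heads; d_k = d_model/heads must be exact |
| `degree_threshold` | 10 | hybrid policies switch to closed-form weighting above this degree |
| `attention_epochs`, `learning_rate`, `batch_size` | 100, 1e-3, 32 | Adam training of the distance regressor |
| `out_dim` | 128 | PCA target width, matching d_model so fused and baseline spaces are comparable |
| `proportions`, `repeats` | (0.2, 0.4, 0.6, 0.8), 10 | evaluation grid |

Walk/skip-gram defaults are the classic random-walk-embedding settings;
all are configurable.

## Synthetic data: what it emulates, what it does not

Real benchmark networks for this task are external downloads, so the
package generates community-structured graphs in which label identity
drives edge density — the structural assumption the method exploits:

* **Single-label**: a planted-partition (stochastic block model) graph;
  n nodes in near-equal blocks, within-block edge probability `p_in`,
  cross-block `p_out` (< `p_in`), block index = label.
* **Multi-label**: each node draws 1–k labels; a pair sharing at least one
  label connects with `p_in`, otherwise `p_out`. Setting `p_in = p_out`
  degenerates to a label-independent random graph (no-signal control).

Both are bit-reproducible for a fixed seed. They emulate homophilous
community structure with near-uniform degrees. They do **not** emulate
heavy-tailed degree distributions, degree–label correlations, nested or
hierarchical communities, or the label sparsity of real social and
protein-interaction networks. Passing tests on these fixtures therefore
demonstrates the machinery (determinism, contracts, the direction of the
aggregation benefit over the walk-only baseline) — not transferable
accuracy levels on real networks.

One consequence is worth stating plainly: on a clean planted partition,
*every* neighbor of a node shares its label, so the local vector alone is
a near-ideal denoiser and can score slightly **above** the fused
self+local representation — the opposite of the ordering seen on real
networks, where local-only is much weaker than self and fusion is what
pays. The acceptance script reports all four variants so this behavior is
visible rather than hidden.

## Numerical choices

* **Skip-gram trainer** (plain numpy): dynamic context windows (a pair at
  offset k kept with probability (window−k+1)/window), 5 negatives per
  positive from the unigram^0.75 distribution, linear learning-rate decay
  0.025 → 1e-4. Updates run in float32; per-batch scatter-adds are sparse
  one-hot matmuls. Mini-batches are capped at 4× the vocabulary size:
  within a batch every repeat of a row contributes a gradient evaluated
  at the same stale value, so batches large relative to the vocabulary
  compound updates into divergence. Single-threaded and bit-reproducible
  for a fixed seed.
* **Attention training**: manual gradients through masked softmax
  attention and the MLP, Adam (β = 0.9/0.999), seeded shuffling. Padded
  key columns receive a −1e30 logit, so their softmax mass is exactly
  zero; padded output rows are zeroed before the MLP. Loss is averaged
  over non-padded neighbor slots.
* **Weight extraction** is the center (first) row of the attention map,
  restricted to neighbor columns and renormalized — the only row relating
  the center to every neighbor. This makes the weights permutation-
  equivariant in the neighbor order (tested).
* **PCA** is centering-only (no variance scaling: both halves of the
  concatenation live on comparable embedding scales), computed by SVD,
  with each component's sign fixed so its largest-absolute loading is
  positive — removing run-to-run sign flips.
* **Degenerate inputs**: self-loops and duplicate edges are dropped on
  read (counted and logged); isolated nodes yield length-1 walks,
  an empty neighbor context, and take their own self vector as the local
  vector (logged); labels whose training split is one-class are skipped
  by the classifier with a warning and can never be predicted.
* **Splits** are unstratified uniform draws with |train| =
  round(p·N); repeat r uses seed base+r.

## Design choices where the design was open

* The neighbor-truncation sample is drawn once per node per run (seeded),
  not resampled per epoch.
* One global attention model is trained over all padded contexts (the MLP
  input width depends on the fixed context size n, which forces padding
  anyway), rather than one model per node.
* The MLP consumes the attention-transformed value matrix, flattened —
  not the raw attention weights.
* For a single head the attention output feeds the MLP directly; the
  output projection W_out exists only in the multi-head model.
* Multi-head weights are the plain average of per-head weight rows.
* `degree_threshold` for the hybrid policies defaults to `max_neighbors`.
* Node identifiers are opaque strings, never coerced to integers;
  directed input is symmetrized.

## Problem sizes used by the test suite and acceptance script

Unit and property tests run on graphs of 30–90 nodes with 16–32-dim
embeddings. The end-to-end directional check and the acceptance script
use a 300-node, 3-block planted partition (p_in = 0.05, p_out = 0.005)
with walks_per_node = 20, walk_length = 40, window = 10, dim = 128 and
3 skip-gram epochs, evaluated at 20% training with 5 repeats, plus a
200-node multi-label fixture — desk-scale settings at which the
embedding quality saturates on these fixtures (~40 s per pipeline run).

## Known limitations

* Only one-hop neighborhoods are aggregated.
* The skip-gram and attention trainers are CPU-bound numpy; they are
  sized for networks of up to a few thousand nodes, not web-scale graphs.
* Micro-F1 is the only metric; no Macro-F1, AUROC or link prediction.
* The multi-label protocol assumes the true label count is known at test
  time; scores are not comparable to thresholded protocols.
* Alternative first-stage embedders (LINE/node2vec-style) are supported
  only by injecting a pre-computed embedding file, not implemented.
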