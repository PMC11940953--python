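# deewana

Unsupervised network representation learning that couples random-walk
node embeddings with **distance-aware weighted neighborhood aggregation**
and PCA fusion, plus the standard node-classification protocol for
judging the result. Intended for anyone embedding undirected networks —
social graphs, protein–protein interaction networks, citation graphs —
for downstream node classification (e.g. protein-function prediction)
without labels at training time.

## The method

Random-walk embeddings capture global structure but ignore how a node's
immediate neighbors are arranged around it in embedding space. This
package refines them in four feed-forward stages:

1. **Self vectors** — truncated uniform random walks + skip-gram with
   negative sampling give each node v a vector r_v ∈ R^d (d = 128 by
   default).
2. **Neighbor weights** — for each node u and its one-hop neighbors n(u)
   (capped at 10, sampled if larger), Euclidean distances
   d_uv = ‖r_u − r_v‖₂ are turned into weights, either in closed form

       d′_uv = 1 / (1 + e^{d_uv}),   w_uv = e^{d′_uv} / Σ_j e^{d′_uj}

   (mode **N**: the closer the neighbor, the larger the weight; mode **F**
   uses 1/(1+e^{−d}) for the proportional variant), or by one-/multi-head
   self-attention over [r_u; r_v1; …] trained — without labels — to
   regress the same distances, reading the weights off the attention map.
   Hybrid policies (`1H+N`, `MH+N`) use attention for low-degree nodes
   and the closed form above a degree threshold.
3. **Aggregate + fuse** — the local vector r′_u = Σ_v α_uv r_v is
   concatenated after r_u and the 2d-wide result is projected back to d
   dimensions by PCA, giving one unified space.
4. **Evaluate** — repeated random splits, one-vs-rest logistic
   regression, micro-averaged F1 at training proportions 0.2–0.8
   (multi-label nodes predict their top-k_i labels, k_i = true label
   count).

Since the benchmark networks for this task are external downloads, the
package ships seeded generators for community-labeled graphs (planted
partition for single-label, overlapping memberships for multi-label) on
which the whole pipeline is exercised and tested.

## Worked example

```python
import deewana as dw

# a 300-node, 3-community planted-partition graph; block = label
spec = dw.SyntheticSpec(n_nodes=300, n_blocks=3, p_in=0.05, p_out=0.005, seed=7)
edges, labels = dw.make_fixture("single", spec, "fixtures")

cfg = dw.PipelineConfig(
    edgelist=str(edges), labels=str(labels), outdir="out",
    walks_per_node=20, walk_length=40, window=10, dim=128, epochs=3,
    weighting="N", fusion="pca", proportions=(0.2, 0.6), repeats=5, seed=1,
)
result = dw.run_pipeline(cfg)["result"]
print(result.summary)
```

Running `examples/04_full_pipeline.py` (exactly this, plus the walk-only
baseline on the same self-embedding) prints:

```
full pipeline (distance-weighted aggregation + PCA fusion):
 proportion     mean      std
        0.2 0.960833 0.009129
        0.6 0.971667 0.017280
walk-only baseline (same self-embedding):
 proportion  mean      std
        0.2 0.945 0.028928
        0.6 0.970 0.007454
```

Each `mean` is the Micro-F1 over 5 random splits at that training
proportion: with only 20% of nodes labeled for training, distance-weighted
neighborhood aggregation plus PCA fusion lifts Micro-F1 from 0.945 to
0.961 on this graph — the same direction of improvement the method shows
at every proportion. The other scripts in `examples/` walk through the
generators, the closed-form weights and the attention-based weights
individually.

A thin CLI wraps the same pipeline:

```bash
deewana make-fixture --kind single --n-nodes 300 --seed 7 --outdir fixtures
deewana run --edgelist fixtures/single_edges.txt --labels fixtures/single_labels.txt \
            --weighting N --fusion pca --seed 1
```

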