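"""Distance-based neighbor weights and weighted aggregation on a toy graph.

Embeds a small two-community graph, then shows how the closed-form
weighting turns center-neighbor Euclidean distances into aggregation
weights: mode N gives closer neighbors more weight, mode F the opposite.
"""

import numpy as np

import deewana as dw

graph, labels = dw.generate_sbm_graph(dw.SyntheticSpec(60, 2, 0.4, 0.03, seed=3))
corpus = dw.simulate_walks(graph, walks_per_node=10, walk_length=20, seed=3)
emb = dw.train_skipgram(corpus, d_model=32, window=5, epochs=3, seed=3)

center = graph.nodes[0]
ctx = dw.neighbor_context(graph, emb, center, max_neighbors=5, seed=3)
print(f"center {center}: degree {ctx.full_degree}, "
      f"{len(ctx.neighbors)} neighbors in context")
print("distances:", np.round(ctx.distances, 3))

w_n = dw.nonlearning_weights(ctx, "N")
w_f = dw.nonlearning_weights(ctx, "F")
print("mode N weights (closer => larger):", np.round(w_n.weights, 4))
print("mode F weights (farther => larger):", np.round(w_f.weights, 4))

local = dw.weighted_aggregate(ctx, w_n, emb)
print("local vector = weighted neighbor mean; first 4 coords:",
      np.round(local[:4], 4))
print("center self vector,            first 4 coords:",
      np.round(emb.row(center)[:4], 4))
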