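"""Learned neighbor weights: self-attention trained on distance regression.

A multi-head attention model is trained (unsupervised) to predict
center-neighbor Euclidean distances; its attention map then supplies the
aggregation weights. The training loss should drop and the extracted
weights always form a distribution over the real neighbors.
"""

import numpy as np

import deewana as dw

graph, _ = dw.generate_sbm_graph(dw.SyntheticSpec(60, 2, 0.4, 0.03, seed=3))
corpus = dw.simulate_walks(graph, walks_per_node=10, walk_length=20, seed=3)
emb = dw.train_skipgram(corpus, d_model=32, window=5, epochs=3, seed=3)

contexts = [c for c in dw.all_neighbor_contexts(graph, emb, 10, seed=3)
            if c.neighbors]
model = dw.build_attention_model(d_model=32, heads=4, max_neighbors=10, seed=3)
model, history = dw.train_attention(model, contexts, emb,
                                    epochs=30, learning_rate=1e-3, seed=3)
print(f"distance-regression loss: {history[0]:.4f} -> {history[-1]:.4f} "
      f"over {len(history)} epochs")

ctx = contexts[0]
w = dw.attention_weights(model, ctx, emb)
print(f"attention weights for {ctx.center} ({w.mode}):",
      np.round(w.weights, 4), "sum =", round(float(w.weights.sum()), 10))

# hybrid policy: attention for low-degree nodes, closed form above threshold
routed = dw.select_weighting(ctx, "MH+N", model=model,
                             degree_threshold=10, emb=emb)
print("policy MH+N routed this context to:", routed.mode)
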