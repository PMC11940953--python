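"""Generate the two kinds of synthetic community-labeled graphs.

Single-label: planted partition — blocks of nodes, dense inside a block
(p_in), sparse across blocks (p_out), block index = label.
Multi-label: each node holds 1-3 of 5 labels; sharing a label raises the
edge probability from p_out to p_in.
"""

import deewana as dw

spec = dw.SyntheticSpec(n_nodes=300, n_blocks=3, p_in=0.05, p_out=0.005, seed=7)
graph, labels = dw.generate_sbm_graph(spec)
degrees = [graph.degree(v) for v in graph.nodes]
print(f"single-label: {graph.n_nodes} nodes, {graph.n_edges} edges, "
      f"mean degree {sum(degrees) / len(degrees):.2f}, "
      f"labels {labels.label_universe}")

mspec = dw.SyntheticSpec(n_nodes=200, n_blocks=5, p_in=0.08, p_out=0.01,
                         labels_per_node=(1, 3), seed=7)
mgraph, mlabels = dw.generate_multilabel_graph(mspec)
per_node = [len(mlabels[v]) for v in mlabels.nodes()]
print(f"multi-label:  {mgraph.n_nodes} nodes, {mgraph.n_edges} edges, "
      f"avg labels/node {sum(per_node) / len(per_node):.2f}, "
      f"multilabel={mlabels.multilabel}")

# Expected edge count inside one block of 100 at p_in=0.05 is
# 0.05 * C(100,2) = 247.5; three blocks plus sparse cross-block edges.
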