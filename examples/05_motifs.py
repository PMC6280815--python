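"""3-node motif census, randomization significance, rank normalization.

Enumerates the 13 connected 3-node motif classes by their canonical IDs,
counts them in a network with planted feed-forward loops, and tests
significance against degree-preserving edge-swap randomizations.
"""

import networkx as nx
import numpy as np

import tsen

classes = tsen.enumerate_motif_classes(3)
print("3-node motif IDs:", [c.motif_id for c in classes])
print("named:", {c.motif_id: c.label for c in classes if c.label})

# plant 40 feed-forward loops on a sparse random background
g = nx.DiGraph()
rng = np.random.default_rng(0)
for k in range(40):
    g.add_edges_from([(f"a{k}", f"b{k}"), (f"a{k}", f"c{k}"),
                      (f"b{k}", f"c{k}")])
nodes = list(g.nodes)
for _ in range(60):
    u, v = rng.choice(len(nodes), 2, replace=False)
    g.add_edge(nodes[u], nodes[v])

census = tsen.motif_significance(g, n_rand=100, seed=0)
present = {m: c for m, c in census.counts.items() if c}
print("counts:", present)
print("significant at p<=0.05:", census.significant(0.05))

norm = tsen.normalize_across_ranks({
    "phylum": tsen.motif_census(np.zeros((3, 3), int)),
    "family": census,
})
print("normalized abundance of ID 38 by rank:",
      dict(norm.loc[38].round(2)))
# The planted feed-forward loop (ID 38) is counted >= 40 times and flagged
# significant; a normalized abundance of 1 at family rank means the motif
# occurs only at that taxonomic level.
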