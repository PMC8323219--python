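"""Build the label-dependency graph from a tiny annotation table.

Four fundus images annotated with three lesion labels are enough to walk
through every stage: co-occurrence counts, conditional probabilities
P(L_i | L_j), thresholded edges, re-weighted adjacency and the normalized
operator the GCN propagates over.
"""

import numpy as np

from fundusgcn import GraphConfig, build_adjacency

# rows = images, columns = (hemorrhages, hard exudates, soft exudates)
annotations = np.array([
    [1, 1, 0],
    [1, 0, 0],
    [0, 1, 1],
    [1, 1, 0],
])
labels = ["hemorrhages", "hard exudates", "soft exudates"]

graph = build_adjacency(annotations, GraphConfig(tau=0.3, p=0.25))

np.set_printoptions(precision=3, suppress=True)
print("conditional probabilities P(row | column):")
print(graph["P"])
print("\nbinarized edges (P >= 0.3):")
print(graph["A_binary"])
print("\nre-weighted adjacency (diagonal 1-p = 0.75, edges share p = 0.25):")
print(graph["A_reweighted"])
print("\nnormalized operator fed to the GCN:")
print(graph["A_normalized"])
print("\nEach column j of P answers: when lesion j is present, how often is"
      "\nlesion i also present?  Note the asymmetry: soft exudates always"
      "\nco-occur with hard exudates here (P = 1), but not vice versa (1/3).")
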