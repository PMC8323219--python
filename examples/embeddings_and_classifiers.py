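"""From label word-vectors to per-label classifiers and image scores.

Loads a miniature GloVe-style vector table, composes one feature vector per
lesion label (token mean), propagates them through a two-layer GCN over a
toy label graph, and scores a random image feature vector against the
resulting classifiers.
"""

import tempfile
from pathlib import Path

import numpy as np

from fundusgcn import (GCNStack, build_adjacency, build_feature_matrix,
                       gcn_forward, load_word_vectors, predict_labels, score)

VECTORS = """\
hard 0.9 0.1 0.0 0.2
soft 0.1 0.8 0.1 0.3
exudates 0.4 0.4 0.6 0.1
hemorrhages 0.0 0.2 0.9 0.7
"""

with tempfile.TemporaryDirectory() as td:
    path = Path(td) / "vectors.txt"
    path.write_text(VECTORS)
    table = load_word_vectors(path)

labels = ["hard exudates", "soft exudates", "hemorrhages"]
X = build_feature_matrix(labels, table)
print("label feature matrix X (token means, one row per label):")
np.set_printoptions(precision=3, suppress=True)
print(X.matrix)

annotations = np.array([[1, 0, 1], [1, 1, 0], [0, 1, 1], [1, 0, 1]])
A_hat = build_adjacency(annotations)["A_normalized"]

stack = GCNStack(dims=[4, 8, 6], seed=0)   # d=4 -> 8 -> D=6
Z = gcn_forward(X.matrix, A_hat, stack)
print(f"\nclassifier matrix Z: {Z.shape[0]} labels x {Z.shape[1]} features")

F = np.random.default_rng(3).normal(size=6)  # stand-in image feature
raw = score(F, Z)
conf = 1.0 / (1.0 + np.exp(-raw))
print("raw scores y = F Z^T:", np.round(raw, 3))
print("per-label confidence:", np.round(conf, 3))
print("hard predictions (confidence > 0.5):", predict_labels(raw))
print("\nEach row of Z is a classifier for one lesion, shaped by both its"
      "\nword embedding and its neighbours in the co-occurrence graph.")
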