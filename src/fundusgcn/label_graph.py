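"""Label-dependency graph from annotation co-occurrence.

The GCN propagates label embeddings over a graph whose edges encode how often
lesions co-occur in the training annotations.  The pipeline is

    counts  M = Y^T Y                (co-occurrence over binary annotations)
    cond.   P[i, j] = M[i, j] / M[j, j]   i.e.  P(L_i | L_j)
    binary  A'[i, j] = 1 if P[i, j] >= tau else 0
    weight  A[i, j]  = p * A'[i, j] / s_i  (i != j, s_i = row edge count),
            A[i, i]  = 1 - p
    norm    A_hat = D^{-1/2} A D^{-1/2},  D = diag(row sums of A)

Binarization discards weak, noisy conditionals so the graph generalises past
the training split; the re-weighting keeps each label's own feature dominant
(weight 1 - p) while distributing p over its neighbours, which counters the
over-smoothing a dense stochastic operator would cause.  Defaults tau = 0.3,
p = 0.25.

The conditional matrix is genuinely asymmetric (P(i|j) != P(j|i)); no stage
symmetrizes it, so A_hat may be asymmetric too.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "GraphConfig",
    "cooccurrence_counts",
    "conditional_probabilities",
    "binarize",
    "reweight",
    "normalize",
    "build_adjacency",
    "save_matrix",
    "load_matrix",
]


@dataclass
class GraphConfig:
    """Graph-construction parameters.

    tau : binarization threshold on conditional probabilities, in (0, 1).
    p   : re-weighting coefficient — off-diagonal mass per row; the diagonal
          (a label's own feature) keeps 1 - p.  Both defaults follow the
          reference configuration for 8 fundus-lesion labels.
    """

    tau: float = 0.3
    p: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 < self.tau < 1.0:
            raise ValueError(f"tau must be in (0, 1), got {self.tau}")
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"p must be in (0, 1), got {self.p}")


def _check_binary(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y)
    if Y.ndim != 2 or Y.shape[0] < 1:
        raise ValueError("label matrix must be 2-D with at least one sample")
    if not np.isin(Y, (0, 1)).all():
        raise ValueError("label matrix entries must be binary (0/1)")
    return Y.astype(np.int64)


def cooccurrence_counts(Y) -> np.ndarray:
    """N x N co-occurrence counts from an n_samples x N binary matrix.

    Entry (i, j) counts samples carrying both labels; the diagonal holds the
    marginal count of each label.
    """
    Y = _check_binary(Y)
    return Y.T @ Y


def conditional_probabilities(M) -> np.ndarray:
    """P[i, j] = P(L_i | L_j) = M[i, j] / M[j, j].

    Requires every label to occur at least once — the conditional is undefined
    for a never-seen label, and the error names the offending index.
    """
    M = np.asarray(M, dtype=float)
    diag = np.diag(M)
    missing = np.flatnonzero(diag <= 0)
    if missing.size:
        raise ValueError(
            f"labels with zero occurrences (indices {missing.tolist()}): "
            "conditional probabilities undefined"
        )
    return M / diag[np.newaxis, :]


def binarize(P, tau: float) -> np.ndarray:
    """Threshold the conditional matrix: A'[i, j] = 1 iff P[i, j] >= tau.

    Applied uniformly, diagonal included (the diagonal is overwritten by the
    re-weighting stage anyway).  Ties at tau count as edges.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    P = np.asarray(P, dtype=float)
    return (P >= tau).astype(float)


def reweight(A_bin, p: float) -> np.ndarray:
    """Distribute weight p over each row's edges; diagonal gets 1 - p.

    For i != j:  A[i, j] = p * A'[i, j] / s_i  with  s_i = sum_{j != i} A'[i, j],
    so entries that binarization zeroed stay zero and each row with at least
    one edge sums to exactly 1.  A row with no edges keeps only its diagonal
    1 - p (not renormalized).
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    A_bin = np.asarray(A_bin, dtype=float)
    n = A_bin.shape[0]
    off = A_bin.copy()
    np.fill_diagonal(off, 0.0)
    s = off.sum(axis=1)
    A = np.zeros_like(off)
    connected = s > 0
    A[connected] = p * off[connected] / s[connected, np.newaxis]
    A[np.diag_indices(n)] = 1.0 - p
    return A


def normalize(A) -> np.ndarray:
    """Symmetric degree normalization A_hat = D^{-1/2} A D^{-1/2}.

    D is the diagonal of row sums; the diagonal of A is already populated by
    the re-weighting stage, so no self-loops are added here.
    """
    A = np.asarray(A, dtype=float)
    d = A.sum(axis=1)
    if np.any(d <= 0):
        bad = np.flatnonzero(d <= 0)
        raise ValueError(f"non-positive row sums at indices {bad.tolist()}")
    inv_sqrt = 1.0 / np.sqrt(d)
    return inv_sqrt[:, np.newaxis] * A * inv_sqrt[np.newaxis, :]


def build_adjacency(Y, config: GraphConfig | None = None) -> dict[str, np.ndarray]:
    """Run the full pipeline on a binary annotation matrix.

    Returns all four stages keyed ``P``, ``A_binary``, ``A_reweighted``,
    ``A_normalized``.  Y should come from the *training* split only so the
    graph never sees held-out co-occurrence.
    """
    config = config or GraphConfig()
    M = cooccurrence_counts(Y)
    P = conditional_probabilities(M)
    A_bin = binarize(P, config.tau)
    A_rw = reweight(A_bin, config.p)
    A_hat = normalize(A_rw)
    return {
        "counts": M.astype(float),
        "P": P,
        "A_binary": A_bin,
        "A_reweighted": A_rw,
        "A_normalized": A_hat,
    }


def save_matrix(path, matrix: np.ndarray, labels: list[str]) -> None:
    """Write a labelled square matrix as TSV with a label-name header row."""
    matrix = np.asarray(matrix, dtype=float)
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(labels) + "\n")
        for row in matrix:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def load_matrix(path) -> tuple[np.ndarray, list[str]]:
    """Read a matrix written by :func:`save_matrix`."""
    with Path(path).open(encoding="utf-8") as fh:
        labels = fh.readline().rstrip("\n").split("\t")
        rows = [[float(v) for v in line.split("\t")] for line in fh if line.strip()]
    matrix = np.array(rows, dtype=float)
    if matrix.shape != (len(labels), len(labels)):
        raise ValueError(f"{path}: matrix shape {matrix.shape} does not match "
                         f"{len(labels)} header labels")
    return matrix, labels
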