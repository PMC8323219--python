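"""Label feature matrices from word embeddings.

The GCN head consumes one feature vector per lesion label.  In the intended
workflow these come from pre-trained GloVe-style word vectors: each label name
is tokenized, the vectors of its tokens are looked up and averaged, and the
per-label vectors are stacked into the N x d matrix ``X`` that seeds the graph
convolution.  A Gaussian random matrix is available as a control baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WordVectorTable",
    "LabelFeatureMatrix",
    "load_word_vectors",
    "compose_label_vector",
    "build_feature_matrix",
    "random_feature_matrix",
]

logger = logging.getLogger(__name__)


class EmbeddingFormatError(ValueError):
    """Malformed word-vector file or label lookup failure."""


@dataclass
class WordVectorTable:
    """Mapping from token to a fixed-dimension embedding vector."""

    vectors: dict[str, np.ndarray]
    dim: int

    def __post_init__(self) -> None:
        if self.dim <= 0:
            raise ValueError("embedding dimension must be positive")

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors[token]

    def __len__(self) -> int:
        return len(self.vectors)


@dataclass
class LabelFeatureMatrix:
    """N x d feature matrix with its canonical label order.

    Row ``i`` is the feature vector of ``labels[i]``; every consumer of the
    matrix (graph construction, GCN, metric reports) uses this same order.
    """

    labels: list[str] = field(default_factory=list)
    matrix: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.labels):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("label names must be unique")

    @property
    def n_labels(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


def load_word_vectors(path, expected_dim: int | None = None) -> WordVectorTable:
    """Parse a GloVe plain-text vector file.

    Each line holds a token followed by ``d`` whitespace-separated floats.
    The word2vec text dialect, whose first line is a two-integer
    ``<count> <dim>`` header, is detected and skipped automatically — both
    dialects circulate under the name "GloVe format".

    Parameters
    ----------
    path
        UTF-8 text file of vectors.
    expected_dim
        If given, the file's dimension must match it.
    """
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            parts = raw.rstrip("\n").split()
            if not parts:
                continue
            if lineno == 1 and len(parts) == 2 and _all_ints(parts):
                continue  # word2vec text header
            token, values = parts[0], parts[1:]
            if not values:
                raise EmbeddingFormatError(
                    f"{path}: line {lineno} has no vector values"
                )
            try:
                vec = np.array([float(v) for v in values], dtype=float)
            except ValueError as exc:
                raise EmbeddingFormatError(
                    f"{path}: line {lineno} has a non-numeric value"
                ) from exc
            if dim is None:
                dim = vec.size
            elif vec.size != dim:
                raise EmbeddingFormatError(
                    f"{path}: line {lineno} has dimension {vec.size}, "
                    f"expected {dim}"
                )
            vectors[token] = vec
    if dim is None or not vectors:
        raise EmbeddingFormatError(f"{path}: no vectors found")
    if expected_dim is not None and dim != expected_dim:
        raise EmbeddingFormatError(
            f"{path}: dimension {dim} does not match expected {expected_dim}"
        )
    return WordVectorTable(vectors=vectors, dim=dim)


def _all_ints(parts: list[str]) -> bool:
    try:
        return all(float(p) == int(float(p)) and "." not in p for p in parts)
    except ValueError:
        return False


def compose_label_vector(label: str, table: WordVectorTable) -> np.ndarray:
    """Average the embeddings of a label's tokens.

    The label is lowercased and split on whitespace; tokens absent from the
    table are skipped with a warning.  Averaging is order-invariant and keeps
    multi-word labels such as "cup disc ratio" on the same scale as single
    tokens.

    Raises
    ------
    KeyError
        If no token of the label is present in the table.
    """
    if not label or not label.strip():
        raise ValueError("label must be a non-empty string")
    tokens = label.lower().split()
    found = [t for t in tokens if t in table]
    missing = [t for t in tokens if t not in table]
    if not found:
        raise KeyError(
            f"no token of label {label!r} found in vector table "
            f"(missing: {missing})"
        )
    if missing:
        logger.warning(
            "label %r: tokens %s not in vector table; averaging over %s",
            label, missing, found,
        )
    return np.mean([table[t] for t in found], axis=0)


def build_feature_matrix(labels, table: WordVectorTable) -> LabelFeatureMatrix:
    """Stack per-label composed vectors into the N x d matrix X.

    Fails atomically: if any label has no token in the table, no matrix is
    produced and the error names the label.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("need at least one label")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate label names in label list")
    rows = []
    for label in labels:
        try:
            rows.append(compose_label_vector(label, table))
        except KeyError as exc:
            raise KeyError(f"label {label!r}: {exc.args[0]}") from exc
    return LabelFeatureMatrix(labels=labels, matrix=np.vstack(rows))


def random_feature_matrix(n_labels: int, dim: int, seed: int,
                          labels=None) -> LabelFeatureMatrix:
    """Gaussian control baseline: i.i.d. standard-normal N x d matrix."""
    if n_labels <= 0 or dim <= 0:
        raise ValueError("n_labels and dim must be positive")
    rng = np.random.default_rng(seed)
    matrix = rng.standard_normal((n_labels, dim))
    if labels is None:
        labels = [f"label_{i}" for i in range(n_labels)]
    labels = list(labels)
    if len(labels) != n_labels:
        raise ValueError("labels length must equal n_labels")
    return LabelFeatureMatrix(labels=labels, matrix=matrix)
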