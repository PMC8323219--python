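"""Loss, dataset splitting and the end-to-end fitting loop.

The model couples the image branch with the graph head: an image's feature
vector F (from the backbone) is scored against the label classifiers Z (from
the GCN over the label graph) as y = F Z^T, and trained with the multi-label
soft-margin loss — per-label binary cross-entropy on the logits, averaged
over labels and batch.  SGD uses momentum, L2 weight decay and two learning
rates: a lower one for the backbone convolutions, a higher one for the
downsampling convolutions and the GCN weights.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .backbone import BackboneConfig, FeatureExtractor, prepare_images
from .gcn_head import GCNStack, score
from .metrics import evaluate_predictions
from .nn import SGD, Param, sigmoid

__all__ = [
    "OptimConfig",
    "SplitSpec",
    "multilabel_softmargin_loss",
    "loss_gradient",
    "predict_labels",
    "split_dataset",
    "LesionGCNModel",
    "fit",
]


@dataclass
class OptimConfig:
    """SGD settings; the two rates mirror the pretrained-backbone convention
    (backbone 0.01, everything else 0.1)."""

    momentum: float = 0.9
    weight_decay: float = 1e-4
    lr_backbone: float = 0.01
    lr_head: float = 0.1
    epochs: int = 30
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_backbone <= 0 or self.lr_head <= 0:
            raise ValueError("learning rates must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be at least 1")


@dataclass
class SplitSpec:
    """Train/validation/test fractions (default 0.70/0.15/0.15) and seed."""

    train: float = 0.70
    val: float = 0.15
    test: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.train + self.val + self.test
        if not np.isclose(total, 1.0):
            raise ValueError(f"split fractions must sum to 1, got {total}")


def multilabel_softmargin_loss(y_pred, y) -> float:
    """Multi-label one-versus-all logistic loss.

    Per sample: -(1/N) sum_i [ y_i log sigma(x_i) + (1-y_i) log(1-sigma(x_i)) ],
    then the mean over the batch.  Evaluated in the numerically stable
    softplus form max(x,0) - x*y + log(1 + exp(-|x|)).
    """
    x = np.atleast_2d(np.asarray(y_pred, dtype=float))
    t = np.atleast_2d(np.asarray(y))
    if x.shape != t.shape:
        raise ValueError(f"shape mismatch: scores {x.shape} vs labels {t.shape}")
    if not np.isin(t, (0, 1)).all():
        raise ValueError("labels must be binary")
    t = t.astype(float)
    elem = np.maximum(x, 0.0) - x * t + np.log1p(np.exp(-np.abs(x)))
    return float(elem.mean(axis=1).mean())


def loss_gradient(y_pred, y) -> np.ndarray:
    """d loss / d scores = (sigma(x) - y) / (B * N)."""
    x = np.atleast_2d(np.asarray(y_pred, dtype=float))
    t = np.atleast_2d(np.asarray(y, dtype=float))
    b, n = x.shape
    return (sigmoid(x) - t) / (b * n)


def predict_labels(y_pred, threshold: float = 0.5) -> np.ndarray:
    """Hard labels: positive iff sigmoid(score) exceeds the threshold.

    The comparison is strict, so at the default 0.5 a raw score of exactly 0
    is negative; a general threshold t corresponds to score > log(t/(1-t)).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    scores = np.asarray(y_pred, dtype=float)
    cut = np.log(threshold / (1.0 - threshold))
    return (scores > cut).astype(np.int64)


def split_dataset(manifest: pd.DataFrame, spec: SplitSpec
                  ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Seeded shuffle then contiguous cut into train/val/test manifests.

    The three parts are an exact partition (sizes differ from the ideal
    fractions only by rounding); each output carries a ``split`` column.
    Splitting is by row (image); patient-level grouping is available by
    pre-aggregating on ``patient_id`` before calling.
    """
    n = len(manifest)
    if n < 3:
        raise ValueError("need at least 3 samples to split three ways")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    cut1 = int(round(spec.train * n))
    cut2 = int(round((spec.train + spec.val) * n))
    parts = []
    for name, idx in (("train", order[:cut1]), ("val", order[cut1:cut2]),
                      ("test", order[cut2:])):
        part = manifest.iloc[np.sort(idx)].copy()
        part["split"] = name
        part.attrs.update(manifest.attrs)
        parts.append(part)
    return tuple(parts)


class LesionGCNModel:
    """Image branch + GCN head with a fixed label graph and embedding matrix."""

    def __init__(self, backbone_config: BackboneConfig, gcn_dims: list[int],
                 X: np.ndarray, A_hat: np.ndarray, labels: list[str],
                 seed: int = 0, slope: float = 0.2):
        X = np.asarray(X, dtype=float)
        A_hat = np.asarray(A_hat, dtype=float)
        if gcn_dims[0] != X.shape[1]:
            raise ValueError(
                f"GCN input dim {gcn_dims[0]} != embedding dim {X.shape[1]}")
        if gcn_dims[-1] != backbone_config.feature_dim:
            raise ValueError(
                f"GCN output dim {gcn_dims[-1]} != backbone feature dim "
                f"{backbone_config.feature_dim}")
        if X.shape[0] != A_hat.shape[0] or X.shape[0] != len(labels):
            raise ValueError("label count mismatch between X, A_hat, labels")
        self.extractor = FeatureExtractor(backbone_config, seed=seed)
        self.stack = GCNStack(gcn_dims, seed=seed + 1, slope=slope)
        self.X = X
        self.A_hat = A_hat
        self.labels = list(labels)
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return self.extractor.params + self.stack.params

    def forward(self, images: np.ndarray) -> np.ndarray:
        """(B, 3, S, S) images -> (B, N) raw scores."""
        F = self.extractor.features(images)
        Z = self.stack.forward(self.X, self.A_hat)
        self._cache = (F, Z)
        return score(F, Z)

    def backward(self, dscores: np.ndarray) -> None:
        F, Z = self._cache
        dF = dscores @ Z
        dZ = dscores.T @ F
        self.stack.backward(dZ)
        self.extractor.backward(dF)

    def predict_scores(self, images: np.ndarray,
                       batch_size: int = 32) -> np.ndarray:
        out = []
        for start in range(0, images.shape[0], batch_size):
            out.append(self.forward(images[start:start + batch_size]))
        return np.vstack(out)

    def get_state(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.params}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params:
            p.value[...] = state[p.name]

    def save(self, path) -> None:
        np.savez(path, **self.get_state())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.set_state({k: data[k] for k in data.files})


@dataclass
class FitResult:
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_cf1: float = -1.0


def fit(model: LesionGCNModel, train_images: np.ndarray,
        train_labels: np.ndarray, val_images: np.ndarray | None,
        val_labels: np.ndarray | None, cfg: OptimConfig) -> FitResult:
    """SGD training loop with per-epoch validation OF1/CF1 logging.

    ``train_images`` must already be prepared as (B, 3, S, S) floats (see
    :func:`fundusgcn.backbone.prepare_images`).  The best-validation-CF1
    weights are restored into the model before returning.
    """
    if train_images.shape[0] == 0:
        raise ValueError("empty training split")
    opt = SGD(model.params,
              lr_by_group={"backbone": cfg.lr_backbone, "head": cfg.lr_head},
              momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    n = train_images.shape[0]
    result = FitResult()
    best_state = None
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            opt.zero_grad()
            scores = model.forward(train_images[idx])
            losses.append(multilabel_softmargin_loss(scores,
                                                     train_labels[idx]))
            model.backward(loss_gradient(scores, train_labels[idx]))
            opt.step()
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_images is not None and val_images.shape[0] > 0:
            vscores = model.predict_scores(val_images)
            vreport = evaluate_predictions(val_labels,
                                           predict_labels(vscores),
                                           scores=None)
            entry["val_of1"] = vreport.of1
            entry["val_cf1"] = vreport.cf1
            if vreport.cf1 > result.best_val_cf1:
                result.best_val_cf1 = vreport.cf1
                result.best_epoch = epoch
                best_state = copy.deepcopy(model.get_state())
        result.history.append(entry)
    if best_state is not None:
        model.set_state(best_state)
    return result
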