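"""End-to-end experiment driver.

Runs the full method on a (typically synthetic) dataset: generate or load a
manifest, split it, build the label graph from the *training* annotations
only, construct the label feature matrix, train the coupled CNN + GCN model
and evaluate the held-out split with the OF1/CF1/Acc/AUC suite.  The command
line and the acceptance experiments are thin wrappers over these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import data as data_io
from .backbone import BackboneConfig, prepare_images, small_config
from .embeddings import (LabelFeatureMatrix, build_feature_matrix,
                         load_word_vectors, random_feature_matrix)
from .label_graph import GraphConfig, build_adjacency, save_matrix
from .metrics import MetricReport, evaluate_predictions
from .nn import SGD
from .synthetic_data import (ProfileMixture, RenderSpec, generate_dataset,
                             two_profile_mixture)
from .training import (LesionGCNModel, OptimConfig, SplitSpec, fit,
                       loss_gradient, multilabel_softmargin_loss,
                       predict_labels, split_dataset)

__all__ = ["ExperimentConfig", "ExperimentResult", "derive_seeds",
           "run_experiment", "overfit_one_batch", "scaled_down_config"]


def derive_seeds(seed: int, names: tuple[str, ...] = (
        "data", "split", "init", "optim")) -> dict[str, int]:
    """Fan one global seed out into independent sub-seeds (< 2^31)."""
    state = np.random.SeedSequence(seed).generate_state(len(names))
    return {name: int(s % (2 ** 31)) for name, s in zip(names, state)}


@dataclass
class ExperimentConfig:
    """Everything one training run needs, with scaled-down defaults."""

    n_images: int = 600
    mixture: ProfileMixture = field(default_factory=two_profile_mixture)
    render: RenderSpec = field(default_factory=lambda: RenderSpec(size=64))
    graph: GraphConfig = field(default_factory=GraphConfig)
    embedding_dim: int = 16
    gcn_dims: tuple[int, ...] = (16, 32, 64)
    backbone: BackboneConfig = field(
        default_factory=lambda: small_config(feature_dim=64))
    optim: OptimConfig = field(default_factory=lambda: OptimConfig(epochs=30))
    split: SplitSpec = field(default_factory=SplitSpec)


def scaled_down_config(seed: int = 0, epochs: int = 30) -> ExperimentConfig:
    """The scaled-down study conditions: 600 images, 64 px, 4 labels."""
    return ExperimentConfig(optim=OptimConfig(epochs=epochs, seed=seed))


@dataclass
class ExperimentResult:
    report: MetricReport
    model: LesionGCNModel
    history: list[dict]
    graph: dict[str, np.ndarray]
    manifest: pd.DataFrame
    splits: tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]


def _feature_matrix(config: ExperimentConfig, labels: list[str],
                    seed: int, source: str = "random",
                    vectors_path=None) -> LabelFeatureMatrix:
    if source == "random":
        return random_feature_matrix(len(labels), config.embedding_dim,
                                     seed=seed, labels=labels)
    if source == "glove_text":
        table = load_word_vectors(vectors_path,
                                  expected_dim=config.embedding_dim)
        return build_feature_matrix(labels, table)
    raise ValueError(f"unknown embedding source {source!r}")


def run_experiment(config: ExperimentConfig, work_dir, seed: int,
                   embedding_source: str = "random",
                   vectors_path=None) -> ExperimentResult:
    """Simulate, split, build graph, train, evaluate — one seeded run."""
    seeds = derive_seeds(seed)
    work_dir = Path(work_dir)
    manifest = generate_dataset(config.n_images, config.mixture,
                                config.render, work_dir, seed=seeds["data"])
    manifest.attrs["base_dir"] = str(work_dir)
    labels = list(config.mixture.labels)

    split_spec = SplitSpec(train=config.split.train, val=config.split.val,
                           test=config.split.test, seed=seeds["split"])
    train_m, val_m, test_m = split_dataset(manifest, split_spec)

    graph = build_adjacency(data_io.label_matrix(train_m, labels),
                            config.graph)
    X = _feature_matrix(config, labels, seeds["init"], embedding_source,
                        vectors_path)

    model = LesionGCNModel(config.backbone, list(config.gcn_dims),
                           X.matrix, graph["A_normalized"], labels,
                           seed=seeds["init"])

    images = {}
    for name, part in (("train", train_m), ("val", val_m), ("test", test_m)):
        raw = data_io.load_images(part, base_dir=work_dir,
                                  expected_size=config.backbone.input_size)
        images[name] = prepare_images(raw, config.backbone)

    optim = OptimConfig(momentum=config.optim.momentum,
                        weight_decay=config.optim.weight_decay,
                        lr_backbone=config.optim.lr_backbone,
                        lr_head=config.optim.lr_head,
                        epochs=config.optim.epochs,
                        batch_size=config.optim.batch_size,
                        seed=seeds["optim"])
    result = fit(model, images["train"], data_io.label_matrix(train_m, labels),
                 images["val"], data_io.label_matrix(val_m, labels), optim)

    test_scores = model.predict_scores(images["test"])
    report = evaluate_predictions(data_io.label_matrix(test_m, labels),
                                  predict_labels(test_scores),
                                  scores=test_scores, labels=labels)
    return ExperimentResult(report=report, model=model,
                            history=result.history, graph=graph,
                            manifest=manifest,
                            splits=(train_m, val_m, test_m))


def overfit_one_batch(config: ExperimentConfig, work_dir, seed: int,
                      batch_size: int = 8, steps: int = 800
                      ) -> tuple[float, MetricReport]:
    """Sanity check: drive one training batch to memorisation.

    Trains a fresh model on a single batch until (or up to ``steps``) the
    batch is predicted perfectly; returns the final loss and the batch's
    metric report, whose OF1 should be 1.
    """
    seeds = derive_seeds(seed)
    work_dir = Path(work_dir)
    mix = config.mixture
    manifest = generate_dataset(batch_size, mix, config.render, work_dir,
                                seed=seeds["data"])
    labels = list(mix.labels)
    Y = data_io.label_matrix(manifest, labels)
    raw = data_io.load_images(manifest, base_dir=work_dir)
    imgs = prepare_images(raw, config.backbone)

    X = random_feature_matrix(len(labels), config.embedding_dim,
                              seed=seeds["init"], labels=labels)
    graph = build_adjacency(np.maximum(Y, _ensure_occurrence(Y)),
                            config.graph)
    model = LesionGCNModel(config.backbone, list(config.gcn_dims), X.matrix,
                           graph["A_normalized"], labels, seed=seeds["init"])
    opt = SGD(model.params, lr_by_group={"backbone": 0.01, "head": 0.1},
              momentum=0.9, weight_decay=0.0)
    loss = np.inf
    best_wrong = np.inf
    best_state = None
    for _ in range(steps):
        opt.zero_grad()
        scores = model.forward(imgs)
        loss = multilabel_softmargin_loss(scores, Y)
        wrong = int((predict_labels(scores) != Y).sum())
        if wrong < best_wrong:
            best_wrong = wrong
            best_state = model.get_state()
        if wrong == 0:
            break
        model.backward(loss_gradient(scores, Y))
        opt.step()
    if best_state is not None:
        model.set_state(best_state)
    scores = model.predict_scores(imgs)
    report = evaluate_predictions(Y, predict_labels(scores), scores=scores,
                                  labels=labels)
    return float(loss), report


def _ensure_occurrence(Y: np.ndarray) -> np.ndarray:
    """Pad a tiny batch so every label occurs at least once for the graph."""
    pad = np.zeros_like(Y)
    missing = Y.sum(axis=0) == 0
    if missing.any():
        pad[0, missing] = 1
    return pad


def save_graph_artifacts(graph: dict[str, np.ndarray], labels: list[str],
                         out_dir) -> None:
    """Serialize all four graph stages as labelled TSV matrices."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = {"P": "conditional_probabilities.tsv",
             "A_binary": "adjacency_binary.tsv",
             "A_reweighted": "adjacency_reweighted.tsv",
             "A_normalized": "adjacency_normalized.tsv"}
    for key, fname in names.items():
        save_matrix(out_dir / fname, graph[key], labels)
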