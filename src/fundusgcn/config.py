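"""YAML run configuration: schema validation and object construction.

One human-editable file drives every command; unknown keys are rejected so
typos fail loudly.  CLI flags override file values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .backbone import (BackboneConfig, fundus1024_config, small_config,
                       tiny_config)
from .label_graph import GraphConfig
from .synthetic_data import (DEFAULT_LABELS, ProfileMixture, RenderSpec,
                             default_mixture, two_profile_mixture)
from .training import OptimConfig, SplitSpec

__all__ = ["RunConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


_PRESETS = {"tiny": tiny_config, "small": small_config,
            "fundus1024": fundus1024_config}
_MIXTURES = {"default": default_mixture, "two_profile": two_profile_mixture}


@dataclass
class RunConfig:
    """Validated contents of one run's YAML file."""

    seed: int = 0
    out_dir: str = "runs/run"
    labels: list[str] = field(default_factory=lambda: list(DEFAULT_LABELS))
    manifest: str | None = None
    n_images: int = 600
    mixture: ProfileMixture = field(default_factory=default_mixture)
    render: RenderSpec = field(default_factory=RenderSpec)
    graph: GraphConfig = field(default_factory=GraphConfig)
    embedding_source: str = "random"
    embedding_dim: int = 16
    vectors_path: str | None = None
    gcn_dims: list[int] = field(default_factory=lambda: [16, 32, 64])
    gcn_slope: float = 0.2
    backbone: BackboneConfig = field(default_factory=small_config)
    optim: OptimConfig = field(default_factory=OptimConfig)
    split: SplitSpec = field(default_factory=SplitSpec)


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")


def load_config(path) -> RunConfig:
    """Parse and validate a YAML config file into a :class:`RunConfig`."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys(raw, {"seed", "out_dir", "labels", "manifest", "n_images",
                      "mixture", "render", "graph", "embeddings", "gcn",
                      "backbone", "optim", "split"}, "config")
    cfg = RunConfig()
    cfg.seed = int(raw.get("seed", cfg.seed))
    cfg.out_dir = str(raw.get("out_dir", cfg.out_dir))
    if "manifest" in raw and raw["manifest"] is not None:
        cfg.manifest = str(raw["manifest"])
    cfg.n_images = int(raw.get("n_images", cfg.n_images))

    mix_spec = raw.get("mixture", "default")
    if isinstance(mix_spec, str):
        if mix_spec not in _MIXTURES:
            raise ConfigError(f"unknown mixture preset {mix_spec!r}")
        cfg.mixture = _MIXTURES[mix_spec]()
    else:
        _check_keys(mix_spec, {"weights", "probs", "labels"}, "mixture")
        cfg.mixture = ProfileMixture(**mix_spec)
    cfg.labels = list(raw.get("labels", cfg.mixture.labels))

    if "render" in raw:
        _check_keys(raw["render"], {"size", "noise", "contrast", "anchored"},
                    "render")
        cfg.render = RenderSpec(**raw["render"])
    if "graph" in raw:
        _check_keys(raw["graph"], {"tau", "p"}, "graph")
        cfg.graph = GraphConfig(**raw["graph"])
    if "embeddings" in raw:
        emb = raw["embeddings"]
        _check_keys(emb, {"source", "dim", "path"}, "embeddings")
        cfg.embedding_source = emb.get("source", "random")
        if cfg.embedding_source not in ("random", "glove_text"):
            raise ConfigError(
                f"embedding source must be random or glove_text, got "
                f"{cfg.embedding_source!r}")
        cfg.embedding_dim = int(emb.get("dim", cfg.embedding_dim))
        cfg.vectors_path = emb.get("path")
        if cfg.embedding_source == "glove_text" and not cfg.vectors_path:
            raise ConfigError("glove_text embeddings require a path")
    if "gcn" in raw:
        _check_keys(raw["gcn"], {"dims", "slope"}, "gcn")
        cfg.gcn_dims = [int(d) for d in raw["gcn"].get("dims", cfg.gcn_dims)]
        cfg.gcn_slope = float(raw["gcn"].get("slope", cfg.gcn_slope))
    if "backbone" in raw:
        bb = raw["backbone"]
        _check_keys(bb, {"preset", "feature_dim"}, "backbone")
        preset = bb.get("preset", "small")
        if preset not in _PRESETS:
            raise ConfigError(f"unknown backbone preset {preset!r}")
        if preset == "small" and "feature_dim" in bb:
            cfg.backbone = small_config(int(bb["feature_dim"]))
        else:
            cfg.backbone = _PRESETS[preset]()
    if "optim" in raw:
        _check_keys(raw["optim"], {"momentum", "weight_decay", "lr_backbone",
                                   "lr_head", "epochs", "batch_size"},
                    "optim")
        cfg.optim = OptimConfig(**raw["optim"])
    if "split" in raw:
        _check_keys(raw["split"], {"train", "val", "test"}, "split")
        cfg.split = SplitSpec(**raw["split"])

    if cfg.gcn_dims[0] != cfg.embedding_dim:
        raise ConfigError(
            f"gcn dims start at {cfg.gcn_dims[0]} but embedding dim is "
            f"{cfg.embedding_dim}")
    if cfg.gcn_dims[-1] != cfg.backbone.feature_dim:
        raise ConfigError(
            f"gcn dims end at {cfg.gcn_dims[-1]} but backbone feature dim "
            f"is {cfg.backbone.feature_dim}")
    return cfg
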