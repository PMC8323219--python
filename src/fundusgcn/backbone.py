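"""Image feature extraction: conv stages -> downsampling -> global max pool.

The image branch turns an RGB fundus-style image into a single D-vector F:

  1. a stack of stride-reducing convolution stages produces C x h x w
     feature maps (the production-scale preset maps a 1024 x 1024 image to
     2048 x 32 x 32);
  2. two 3 x 3 stride-2 convolutions (padding 1, channel-preserving, each
     followed by a leaky rectifier) downsample the maps twice (32 -> 16 -> 8);
  3. adaptive max-pooling takes the per-channel spatial maximum, yielding
     F in R^D.

The backbone is pluggable through :class:`BackboneConfig`: tests and the
scaled-down experiments use a small CNN on 64 x 64 synthetic images, while
``fundus1024_config`` documents the production-scale shape contract.  All
weights are seeded; backbone-stage parameters carry the ``"backbone"`` group
tag (trained at a lower rate), the downsampling convolutions the ``"head"``
tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Conv2d, GlobalMaxPool, LeakyReLU, Param

__all__ = [
    "BackboneConfig",
    "FeatureExtractor",
    "tiny_config",
    "small_config",
    "fundus1024_config",
    "extract_feature_maps",
    "downsample",
    "global_max_pool",
    "prepare_images",
]


@dataclass
class BackboneConfig:
    """Shape specification of the image branch.

    stages : tuple of (out_channels, kernel, stride) for the backbone convs;
             the last stage's channel count is the feature dimension D.
    input_size : expected square input resolution in pixels.
    """

    name: str = "tiny"
    input_size: int = 64
    stages: tuple[tuple[int, int, int], ...] = ((16, 3, 2), (24, 3, 2),
                                                (32, 3, 2), (32, 3, 2))
    # Small negative slope on the rectifiers: with momentum SGD on small
    # batches a plain ReLU branch can die irreversibly (all activations
    # clamp to zero and the image gradient vanishes); 0 recovers plain ReLU.
    activation_slope: float = 0.01

    def __post_init__(self) -> None:
        if self.input_size < 16:
            raise ValueError("input_size must be at least 16")
        if not self.stages:
            raise ValueError("need at least one conv stage")
        stride = self.total_stride
        if self.input_size % stride:
            raise ValueError(
                f"input_size {self.input_size} not a multiple of total "
                f"stride {stride}")

    @property
    def feature_dim(self) -> int:
        return self.stages[-1][0]

    @property
    def total_stride(self) -> int:
        stride = 1
        for _, _, s in self.stages:
            stride *= s
        return stride

    @property
    def map_size(self) -> int:
        return self.input_size // self.total_stride


def tiny_config() -> BackboneConfig:
    """64 px input, total stride 16, D = 32: maps are 32 x 4 x 4."""
    return BackboneConfig(name="tiny", input_size=64,
                          stages=((16, 3, 2), (24, 3, 2), (32, 3, 2),
                                  (32, 3, 2)))


def small_config(feature_dim: int = 64) -> BackboneConfig:
    """64 px input, total stride 8: maps are D x 8 x 8.

    Default configuration for the scaled-down end-to-end experiments.
    """
    return BackboneConfig(name="small", input_size=64,
                          stages=((16, 3, 2), (32, 3, 2), (feature_dim, 3, 2)))


def fundus1024_config() -> BackboneConfig:
    """Production-scale shape preset: 1024 px input -> 2048 x 32 x 32 maps.

    Stride-32 stem and stages ending in a stride-1 expansion to 2048
    channels.  Weights are randomly initialised; at this scale a pretrained
    deep backbone is the practical choice, so this preset documents the
    shape contract rather than a trained model.
    """
    return BackboneConfig(name="fundus1024", input_size=1024,
                          stages=((64, 7, 4), (128, 3, 2), (256, 3, 2),
                                  (512, 3, 2), (2048, 1, 1)))


class FeatureExtractor:
    """Backbone conv stages + two-conv downsampler + global max pool.

    Holds the trainable weights of the image branch; forward/backward
    operate on (B, 3, H, W) float arrays in [0, 1].
    """

    def __init__(self, config: BackboneConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.stage_layers: list = []
        c_in = 3
        for idx, (c_out, k, s) in enumerate(config.stages):
            pad = k // 2
            self.stage_layers.append(Conv2d(
                c_in, c_out, k, stride=s, padding=pad, rng=rng,
                group="backbone", name=f"backbone.conv{idx}"))
            self.stage_layers.append(LeakyReLU(config.activation_slope))
            c_in = c_out
        d = config.feature_dim
        self.down_layers: list = []
        for idx in range(2):
            self.down_layers.append(Conv2d(
                d, d, 3, stride=2, padding=1, rng=rng,
                group="head", name=f"downsample.conv{idx}"))
            self.down_layers.append(LeakyReLU(config.activation_slope))
        self.pool = GlobalMaxPool()

    @property
    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.stage_layers + self.down_layers:
            out.extend(layer.params)
        return out

    # -- forward pieces ----------------------------------------------------

    def extract_feature_maps(self, images: np.ndarray) -> np.ndarray:
        """Run the backbone stages: (B, 3, S, S) -> (B, D, m, m)."""
        if images.ndim != 4 or images.shape[1] != 3:
            raise ValueError(
                f"expected 3-channel (B, 3, H, W) input, got shape "
                f"{images.shape}")
        if images.shape[2] != self.config.input_size or \
                images.shape[3] != self.config.input_size:
            raise ValueError(
                f"expected {self.config.input_size}px square input, got "
                f"{images.shape[2]}x{images.shape[3]}")
        x = images
        for layer in self.stage_layers:
            x = layer.forward(x)
        return x

    def downsample(self, maps: np.ndarray) -> np.ndarray:
        """Two 3x3 stride-2 convs (padding 1) with ReLU; halves h, w twice."""
        if maps.shape[2] < 4 or maps.shape[3] < 4:
            raise ValueError(
                f"maps {maps.shape[2]}x{maps.shape[3]} too small to "
                "downsample twice (need >= 4)")
        x = maps
        for layer in self.down_layers:
            x = layer.forward(x)
        return x

    def features(self, images: np.ndarray) -> np.ndarray:
        """Full image branch: images -> F (B x D)."""
        return self.pool.forward(self.downsample(
            self.extract_feature_maps(images)))

    def backward(self, dF: np.ndarray) -> np.ndarray:
        grad = self.pool.backward(dF)
        for layer in reversed(self.down_layers):
            grad = layer.backward(grad)
        for layer in reversed(self.stage_layers):
            grad = layer.backward(grad)
        return grad


def prepare_images(images: np.ndarray, config: BackboneConfig) -> np.ndarray:
    """Channel-last uint8/float images -> (B, 3, S, S) floats in [0, 1]."""
    images = np.asarray(images)
    if images.ndim == 3:
        images = images[np.newaxis]
    if images.ndim != 4 or images.shape[-1] != 3:
        raise ValueError(f"expected (B, H, W, 3) images, got {images.shape}")
    if images.shape[1] != config.input_size or \
            images.shape[2] != config.input_size:
        raise ValueError(
            f"images are {images.shape[1]}x{images.shape[2]}, config "
            f"expects {config.input_size}")
    x = images.astype(float)
    if images.dtype == np.uint8:
        x /= 255.0
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def extract_feature_maps(images: np.ndarray,
                         extractor: FeatureExtractor) -> np.ndarray:
    """Functional wrapper over :meth:`FeatureExtractor.extract_feature_maps`."""
    return extractor.extract_feature_maps(images)


def downsample(maps: np.ndarray, extractor: FeatureExtractor) -> np.ndarray:
    """Functional wrapper over :meth:`FeatureExtractor.downsample`."""
    return extractor.downsample(maps)


def global_max_pool(maps: np.ndarray) -> np.ndarray:
    """Per-channel maximum over all spatial positions: (B, C, h, w) -> (B, C)."""
    maps = np.asarray(maps, dtype=float)
    if maps.ndim == 3:
        maps = maps[np.newaxis]
        return maps.max(axis=(2, 3))[0]
    return maps.max(axis=(2, 3))
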