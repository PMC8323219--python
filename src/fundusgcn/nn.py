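"""Minimal NumPy neural-network layers with explicit gradients.

The model here is small enough — a compact conv backbone and a two-layer
graph convolution head — that a full autodiff framework would be overkill.
Each layer implements ``forward`` (caching what backward needs) and
``backward`` (returning the input gradient and accumulating parameter
gradients).  Convolution uses im2col so both passes reduce to matrix
products.

Parameters carry a ``group`` tag ("backbone" or "head") so the optimizer can
apply different learning rates to the image-feature extractor and to
everything else, mirroring the common fine-tuning setup.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Param", "Conv2d", "LeakyReLU", "GlobalMaxPool", "SGD",
           "leaky_relu", "sigmoid"]


class Param:
    """A trainable tensor with its gradient buffer and group tag."""

    __slots__ = ("value", "grad", "group", "name")

    def __init__(self, value: np.ndarray, group: str = "head", name: str = ""):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.group = group
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def leaky_relu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def sigmoid(x: np.ndarray) -> np.ndarray:
    # Branch on sign for numerical stability at large |x|.
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _init_conv(rng: np.random.Generator, c_out: int, c_in: int,
               k: int) -> np.ndarray:
    # Uniform +-1/sqrt(fan-in); seeded for reproducibility.
    bound = 1.0 / np.sqrt(c_in * k * k)
    return rng.uniform(-bound, bound, size=(c_out, c_in, k, k))


class Conv2d:
    """2-D convolution, stride/padding configurable, square kernels.

    Input and output layout is (B, C, H, W).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 padding: int = 0, *, rng: np.random.Generator,
                 group: str = "head", name: str = "conv"):
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.W = Param(_init_conv(rng, c_out, c_in, kernel), group, f"{name}.W")
        bound = 1.0 / np.sqrt(c_in * kernel * kernel)
        self.b = Param(rng.uniform(-bound, bound, size=c_out), group,
                       f"{name}.b")
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def out_size(self, size: int) -> int:
        return (size + 2 * self.padding - self.kernel) // self.stride + 1

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.padding
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (B, C, H', W', k, k) strided view, then flatten patches.
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        b, c, ho, wo = win.shape[:4]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, ho * wo, c * k * k)
        return np.ascontiguousarray(cols), (ho, wo)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(
                f"{self.W.name}: expected {self.c_in} input channels, got {c}")
        ho, wo = self.out_size(h), self.out_size(w)
        if ho < 1 or wo < 1:
            raise ValueError(
                f"{self.W.name}: spatial input {h}x{w} too small for "
                f"kernel {self.kernel} stride {self.stride}")
        cols, (ho, wo) = self._im2col(x)
        wmat = self.W.value.reshape(self.c_out, -1)
        out = cols @ wmat.T + self.b.value  # (B, H'W', C_out)
        self._cache = (cols, x.shape, (ho, wo))
        return out.transpose(0, 2, 1).reshape(b, self.c_out, ho, wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, (ho, wo) = self._cache
        b = x_shape[0]
        dflat = dout.reshape(b, self.c_out, ho * wo).transpose(0, 2, 1)
        wmat = self.W.value.reshape(self.c_out, -1)
        self.W.grad += np.einsum("bpc,bpk->ck", dflat, cols).reshape(
            self.W.value.shape)
        self.b.grad += dflat.sum(axis=(0, 1))
        dcols = dflat @ wmat  # (B, H'W', C*k*k)
        return self._col2im(dcols, x_shape, ho, wo)

    def _col2im(self, dcols: np.ndarray, x_shape, ho: int, wo: int):
        b, c, h, w = x_shape
        k, s, p = self.kernel, self.stride, self.padding
        dx_pad = np.zeros((b, c, h + 2 * p, w + 2 * p))
        dpatches = dcols.reshape(b, ho, wo, c, k, k)
        # Scatter-add each kernel offset as a strided slice assignment.
        for ki in range(k):
            for kj in range(k):
                dx_pad[:, :, ki:ki + ho * s:s, kj:kj + wo * s:s] += \
                    dpatches[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        if p:
            return dx_pad[:, :, p:-p, p:-p]
        return dx_pad


class LeakyReLU:
    """Elementwise max(x, slope*x); slope 0 gives a plain ReLU."""

    def __init__(self, slope: float = 0.0):
        if slope < 0:
            raise ValueError("slope must be non-negative")
        self.slope = slope
        self._mask = None

    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, self.slope * dout)


class GlobalMaxPool:
    """Adaptive max-pool to 1x1: per-channel max over all spatial positions."""

    def __init__(self):
        self._cache = None

    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        flat = x.reshape(b, c, h * w)
        idx = flat.argmax(axis=2)
        self._cache = (idx, x.shape)
        return np.take_along_axis(flat, idx[:, :, None], axis=2)[:, :, 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (b, c, h, w) = self._cache
        dx = np.zeros((b, c, h * w))
        np.put_along_axis(dx, idx[:, :, None], dout[:, :, None], axis=2)
        return dx.reshape(b, c, h, w)


class SGD:
    """Stochastic gradient descent with momentum and L2 weight decay.

    ``lr_by_group`` maps a parameter group tag to its learning rate, so the
    backbone and the classification head can train at different rates.
    """

    def __init__(self, params: list[Param], lr_by_group: dict[str, float],
                 momentum: float = 0.9, weight_decay: float = 1e-4):
        self.params = list(params)
        for prm in self.params:
            if prm.group not in lr_by_group:
                raise KeyError(f"no learning rate for group {prm.group!r} "
                               f"(param {prm.name})")
        self.lr_by_group = dict(lr_by_group)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for prm in self.params:
            prm.zero_grad()

    def step(self) -> None:
        for prm, vel in zip(self.params, self._velocity):
            g = prm.grad + self.weight_decay * prm.value
            vel *= self.momentum
            vel += g
            prm.value -= self.lr_by_group[prm.group] * vel
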