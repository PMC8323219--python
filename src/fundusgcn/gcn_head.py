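"""Graph-convolution head: label embeddings -> per-label classifiers.

Each layer propagates node (label) features over the normalized dependency
graph:  H^{l+1} = sigma(A_hat H^l W^l), with LeakyReLU as sigma.  Starting
from the N x d label feature matrix X, the stack produces Z in R^{N x D} —
one D-dimensional classifier per label — and raw prediction scores for an
image feature F in R^D are simply y = F Z^T.

No activation follows the final layer: Z acts as a set of linear classifier
weights and must be free to take negative values.
"""

from __future__ import annotations

import numpy as np

from .nn import Param, leaky_relu

__all__ = ["GCNStack", "gcn_layer", "gcn_forward", "score"]

DEFAULT_SLOPE = 0.2


def gcn_layer(H: np.ndarray, A_hat: np.ndarray, W: np.ndarray,
              apply_activation: bool = True,
              slope: float = DEFAULT_SLOPE) -> np.ndarray:
    """One propagation step sigma(A_hat @ H @ W).

    With ``apply_activation`` False the linear map A_hat @ H @ W is returned
    unactivated (used for the final layer).
    """
    H, A_hat, W = (np.asarray(m, dtype=float) for m in (H, A_hat, W))
    if A_hat.shape[0] != A_hat.shape[1]:
        raise ValueError(f"adjacency must be square, got {A_hat.shape}")
    if H.shape[0] != A_hat.shape[0]:
        raise ValueError(
            f"node count mismatch: H has {H.shape[0]} rows, "
            f"adjacency is {A_hat.shape[0]}x{A_hat.shape[1]}")
    if H.shape[1] != W.shape[0]:
        raise ValueError(
            f"feature dim mismatch: H has {H.shape[1]} columns, "
            f"W expects {W.shape[0]}")
    out = A_hat @ H @ W
    return leaky_relu(out, slope) if apply_activation else out


class GCNStack:
    """A stack of graph-convolution layers with trainable weights.

    Parameters
    ----------
    dims
        Layer widths [d^0, ..., d^L]; d^0 is the embedding dimension and d^L
        the image-feature dimension D.
    seed
        Seeds the uniform +-1/sqrt(fan-in) weight initialisation.
    slope
        LeakyReLU negative slope (default 0.2).
    final_activation
        Whether to activate the last layer's output (default False).
    """

    def __init__(self, dims: list[int], seed: int = 0,
                 slope: float = DEFAULT_SLOPE,
                 final_activation: bool = False):
        if len(dims) < 2:
            raise ValueError("need at least one layer (two dims)")
        if any(d <= 0 for d in dims):
            raise ValueError("all dims must be positive")
        self.dims = list(dims)
        self.slope = slope
        self.final_activation = final_activation
        rng = np.random.default_rng(seed)
        self.weights: list[Param] = []
        for idx, (din, dout) in enumerate(zip(dims[:-1], dims[1:])):
            bound = 1.0 / np.sqrt(din)
            self.weights.append(Param(
                rng.uniform(-bound, bound, size=(din, dout)),
                group="head", name=f"gcn.W{idx}"))
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return self.weights

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def forward(self, X: np.ndarray, A_hat: np.ndarray) -> np.ndarray:
        """Fold the layers over X; returns the classifier matrix Z (N x D)."""
        X = np.asarray(X, dtype=float)
        A_hat = np.asarray(A_hat, dtype=float)
        if X.shape[1] != self.dims[0]:
            raise ValueError(f"X has feature dim {X.shape[1]}, "
                             f"stack expects {self.dims[0]}")
        H = X
        pre_acts, inputs = [], []
        for lidx, W in enumerate(self.weights):
            inputs.append(H)
            pre = A_hat @ H @ W.value
            pre_acts.append(pre)
            last = lidx == len(self.weights) - 1
            if not last or self.final_activation:
                H = leaky_relu(pre, self.slope)
            else:
                H = pre
        self._cache = (A_hat, inputs, pre_acts)
        return H

    def backward(self, dZ: np.ndarray) -> np.ndarray:
        """Backprop through the stack, accumulating weight grads.

        Returns the gradient with respect to X (rarely needed — X is fixed —
        but cheap to provide).
        """
        A_hat, inputs, pre_acts = self._cache
        grad = dZ
        for lidx in range(len(self.weights) - 1, -1, -1):
            last = lidx == len(self.weights) - 1
            if not last or self.final_activation:
                pre = pre_acts[lidx]
                grad = np.where(pre >= 0, grad, self.slope * grad)
            W = self.weights[lidx]
            AH = A_hat @ inputs[lidx]
            W.grad += AH.T @ grad
            grad = A_hat.T @ grad @ W.value.T
        return grad


def gcn_forward(X: np.ndarray, A_hat: np.ndarray,
                stack: GCNStack) -> np.ndarray:
    """Functional wrapper: run the stack on (X, A_hat) and return Z."""
    return stack.forward(X, A_hat)


def score(F: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Raw (pre-sigmoid) prediction scores y = F Z^T.

    ``F`` may be a single D-vector or a B x D batch; the result is a length-N
    vector or a B x N matrix accordingly.
    """
    F = np.asarray(F, dtype=float)
    Z = np.asarray(Z, dtype=float)
    d = F.shape[-1]
    if d != Z.shape[1]:
        raise ValueError(
            f"feature dim {d} does not match classifier dim {Z.shape[1]}")
    return F @ Z.T
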