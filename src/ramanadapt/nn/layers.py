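"""Layer primitives with explicit forward/backward passes.

Conventions
-----------
* Activations are ``float64`` arrays shaped ``(N, C, L)`` (batch, channels,
  length) until the flatten layer, then ``(N, F)``.
* Each layer keeps its parameters in ``self.params`` (name -> array) and
  accumulates gradients into ``self.grads`` under the same names during
  ``backward``.  Arrays are updated in place by the optimizer so references
  held by composite modules stay valid.
* ``forward(x, training)`` caches whatever ``backward`` needs; layers are
  therefore stateful between a forward and the matching backward call.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv1d", "BatchNorm1d", "ReLU", "Flatten", "Linear"]


class Layer:
    """Base class: parameter/gradient bookkeeping shared by all layers."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """1-D convolution (cross-correlation) with 'same'-style padding.

    With kernel size ``k`` (odd), padding ``k // 2`` and stride ``s`` the
    output length is ``ceil(L / s)``.  Bias is optional; it is omitted in
    the spectral model wherever a batch norm follows.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        bias: bool = False,
        *,
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError(f"kernel_size must be odd, got {kernel_size}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.pad = kernel_size // 2
        # He-style init for ReLU networks.
        fan_in = in_channels * kernel_size
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels, kernel_size))
        if bias:
            self.params["b"] = np.zeros(out_channels)
        self._cache: tuple | None = None

    def output_length(self, length: int) -> int:
        return -(-length // self.stride)  # ceil division

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, length = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        l_out = self.output_length(length)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        # Gather patches: (N, C, L_out, k) -> (N, L_out, C*k)
        idx = np.arange(l_out)[:, None] * self.stride + np.arange(self.kernel_size)[None, :]
        cols = xp[:, :, idx]  # (N, C, L_out, k)
        cols = cols.transpose(0, 2, 1, 3).reshape(n, l_out, c * self.kernel_size)
        w2 = self.params["W"].reshape(self.out_channels, -1)  # (C_out, C*k)
        out = cols @ w2.T  # (N, L_out, C_out)
        if "b" in self.params:
            out += self.params["b"]
        self._cache = (cols, x.shape, l_out)
        return out.transpose(0, 2, 1)  # (N, C_out, L_out)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        cols, x_shape, l_out = self._cache
        n, c, length = x_shape
        g = grad_out.transpose(0, 2, 1)  # (N, L_out, C_out)
        w2 = self.params["W"].reshape(self.out_channels, -1)
        gw = np.einsum("nlo,nlf->of", g, cols)
        self.grads["W"] = self.grads.get("W", 0) + gw.reshape(self.params["W"].shape)
        if "b" in self.params:
            self.grads["b"] = self.grads.get("b", 0) + g.sum(axis=(0, 1))
        gcols = g @ w2  # (N, L_out, C*k)
        gcols = gcols.reshape(n, l_out, c, self.kernel_size).transpose(0, 2, 1, 3)
        gx_pad = np.zeros((n, c, length + 2 * self.pad))
        starts = np.arange(l_out) * self.stride
        for j in range(self.kernel_size):
            # Positions for one kernel offset form an arithmetic progression,
            # so fancy-index accumulation is collision-free per offset.
            gx_pad[:, :, starts + j] += gcols[:, :, :, j]
        return gx_pad[:, :, self.pad : self.pad + length]


class BatchNorm1d(Layer):
    """Channel-wise batch normalization over (batch, length) with affine
    parameters and running statistics.

    ``forward(..., training=True)`` uses batch statistics and updates the
    running moments; ``training=False`` normalizes with the stored running
    moments, which is also what test-time adaptation uses while its entropy
    objective updates only the affine ``gamma`` / ``beta``.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.buffers["running_mean"] = np.zeros(channels)
        self.buffers["running_var"] = np.ones(channels)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            m = self.momentum
            count = x.shape[0] * x.shape[2]
            # Running variance uses the unbiased estimate, as is conventional.
            unbiased = var * count / max(count - 1, 1)
            self.buffers["running_mean"] *= 1 - m
            self.buffers["running_mean"] += m * mean
            self.buffers["running_var"] *= 1 - m
            self.buffers["running_var"] += m * unbiased
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None]) * inv_std[:, None]
        self._cache = (xhat, inv_std, training)
        return self.params["gamma"][:, None] * xhat + self.params["beta"][:, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xhat, inv_std, training = self._cache
        g = grad_out
        self.grads["gamma"] = self.grads.get("gamma", 0) + (g * xhat).sum(axis=(0, 2))
        self.grads["beta"] = self.grads.get("beta", 0) + g.sum(axis=(0, 2))
        gxhat = g * self.params["gamma"][:, None]
        if not training:
            # Normalization constants do not depend on the input.
            return gxhat * inv_std[:, None]
        count = g.shape[0] * g.shape[2]
        sum_g = gxhat.sum(axis=(0, 2))
        sum_gx = (gxhat * xhat).sum(axis=(0, 2))
        return (inv_std[:, None] / count) * (
            count * gxhat - sum_g[:, None] - xhat * sum_gx[:, None]
        )


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, *, rng: np.random.Generator) -> None:
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        bound = np.sqrt(1.0 / in_features)
        self.params["W"] = rng.uniform(-bound, bound, size=(out_features, in_features))
        self.params["b"] = rng.uniform(-bound, bound, size=out_features)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.shape[1] != self.in_features:
            raise ValueError(f"expected {self.in_features} features, got {x.shape[1]}")
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.grads["W"] = self.grads.get("W", 0) + grad_out.T @ self._x
        self.grads["b"] = self.grads.get("b", 0) + grad_out.sum(axis=0)
        return grad_out @ self.params["W"]
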