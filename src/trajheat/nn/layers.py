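"""Layers with forward/backward passes on (batch, width, channels) arrays.

Convolutions are 1-D along the time axis; the models' nominal 3x3
kernels act on height-1 inputs, where the off-row taps only ever see
zero padding, so a width-3 kernel is the exact computation.  Pooling is
likewise 1x2 along time (a 2x2 window degenerates on height 1).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Layer", "Conv1D", "ReLU", "MaxPool1D", "Upsample1D", "Flatten", "Dense"]


class Layer:
    """Base class: forward caches what backward needs; params/grads lists."""

    trainable: bool = False

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def params(self) -> list[np.ndarray]:
        return []

    @property
    def grads(self) -> list[np.ndarray]:
        return []


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Conv1D(Layer):
    """Same-padded 1-D convolution: (N, W, C_in) -> (N, W, C_out)."""

    trainable = True

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 *, rng: np.random.Generator):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size
        self.W = glorot_uniform(rng, fan_in, out_channels,
                                (kernel_size, in_channels, out_channels))
        self.b = np.zeros(out_channels)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cols = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel_size
        pad = k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        width = x.shape[1]
        return np.stack([xp[:, i:i + width, :] for i in range(k)], axis=2)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 3 or x.shape[2] != self.in_channels:
            raise ValueError(
                f"Conv1D expects (N, W, {self.in_channels}), got {x.shape}"
            )
        self._cols = self._im2col(x)  # (N, W, k, C_in)
        return np.einsum("nwkc,kco->nwo", self._cols, self.W) + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gW += np.einsum("nwkc,nwo->kco", self._cols, grad)
        self.gb += grad.sum(axis=(0, 1))
        gcols = np.einsum("nwo,kco->nwkc", grad, self.W)
        k = self.kernel_size
        pad = k // 2
        n, width = grad.shape[0], grad.shape[1]
        gxp = np.zeros((n, width + 2 * pad, self.in_channels))
        for i in range(k):
            gxp[:, i:i + width, :] += gcols[:, :, i, :]
        return gxp[:, pad:pad + width, :]

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.gW, self.gb]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool1D(Layer):
    """Max pooling of size 2 along the time axis (width halves)."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, w, c = x.shape
        p = self.pool
        w2 = w // p
        self._in_width = w
        xr = x[:, : w2 * p, :].reshape(n, w2, p, c)
        self._arg = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, w2, c = grad.shape
        p = self.pool
        gx = np.zeros((n, self._in_width, c))
        gxr = gx[:, : w2 * p, :].reshape(n, w2, p, c)
        ni, wi, ci = np.ogrid[:n, :w2, :c]
        gxr[ni, wi, self._arg, ci] = grad
        gx[:, : w2 * p, :] = gxr.reshape(n, w2 * p, c)
        return gx


class Upsample1D(Layer):
    """Nearest-neighbour upsampling by an integer factor along time."""

    def __init__(self, factor: int = 2):
        self.factor = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(x, self.factor, axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, w, c = grad.shape
        f = self.factor
        return grad.reshape(n, w // f, f, c).sum(axis=2)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    trainable = True

    def __init__(self, in_features: int, out_features: int, *, rng: np.random.Generator):
        self.W = glorot_uniform(rng, in_features, out_features,
                                (in_features, out_features))
        self.b = np.zeros(out_features)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.W.shape[0]:
            raise ValueError(f"Dense expects (N, {self.W.shape[0]}), got {x.shape}")
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gW += self._x.T @ grad
        self.gb += grad.sum(axis=0)
        return grad @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.gW, self.gb]
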