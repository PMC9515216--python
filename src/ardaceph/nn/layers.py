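"""Layer primitives with forward caches and analytic backward passes.

Array layout is (N, C, H, W) throughout.  Convolution uses an im2col
lowering to a single matmul; its backward pass scatters gradients back with
strided adds, which keeps everything vectorised.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: parameterless layers override ``params`` with ()."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv2d(Layer):
    """2D convolution with square kernel, stride and zero padding.

    He-normal initialisation from the supplied generator; bias starts at 0.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        padding: int = 1,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        scale = np.sqrt(2.0 / (in_channels * k * k))
        self.W = rng.normal(0.0, scale, (out_channels, in_channels, k, k))
        self.b = np.zeros(out_channels)
        self.stride = stride
        self.padding = padding
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        n, c, h, w = x.shape
        k = self.W.shape[-1]
        p, s = self.padding, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        windows = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = windows.shape[2], windows.shape[3]
        # (N, C, Ho, Wo, k, k) -> (N, C*k*k, Ho*Wo)
        cols = windows.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
        return np.ascontiguousarray(cols), (xp.shape, ho, wo)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cols, (xp_shape, ho, wo) = self._im2col(x)
        o = self.W.shape[0]
        wflat = self.W.reshape(o, -1)
        y = np.einsum("of,nfl->nol", wflat, cols, optimize=True)
        y = y.reshape(x.shape[0], o, ho, wo) + self.b[None, :, None, None]
        if train:
            self._cache = (cols, x.shape, xp_shape, ho, wo)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, xp_shape, ho, wo = self._cache
        n, c, h, w = x_shape
        o = self.W.shape[0]
        k = self.W.shape[-1]
        p, s = self.padding, self.stride
        dyf = dy.reshape(n, o, ho * wo)
        self.dW[...] = np.einsum("nol,nfl->of", dyf, cols, optimize=True).reshape(self.W.shape)
        self.db[...] = dy.sum(axis=(0, 2, 3))
        wflat = self.W.reshape(o, -1)
        dcols = np.einsum("of,nol->nfl", wflat, dyf, optimize=True)
        dcols = dcols.reshape(n, c, k, k, ho, wo)
        dxp = np.zeros(xp_shape)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, :, i, j]
        return dxp[:, :, p : p + h, p : p + w]

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C); backward spreads gradient uniformly."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], (n, c, h, w)) / (h * w)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_features)
        self.W = rng.normal(0.0, scale, (out_features, in_features))
        self.b = np.zeros(out_features)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW[...] = dy.T @ self._x
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size
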