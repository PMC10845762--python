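"""Minimal CNN building blocks on numpy arrays with hand-written backprop.

Only what the two artifact-reduction networks need: 2-D convolution (same or
valid padding, arbitrary stride), ReLU and nearest-neighbor 2x up-sampling.
All arrays are ``(batch, channels, height, width)`` float64.  Each layer
instance caches what its backward pass needs, so a layer object must be used
exactly once per forward pass of the enclosing network.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Param", "Conv2d", "ReLU", "Upsample2x"]


class Param:
    """A learnable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray, dtype=np.float32):
        self.value = np.asarray(value, dtype=dtype)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Conv2d:
    """2-D convolution (cross-correlation) via im2col.

    ``pad`` is symmetric zero padding; kernel 3 with pad 1 and stride 1 keeps
    the spatial size, kernel 2 with stride 2 and pad 0 halves it (the strided
    down-sampling the networks use instead of max-pooling).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        pad: int | None = None,
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
        dtype=np.float32,
    ):
        self.cin, self.cout = in_channels, out_channels
        self.k, self.stride = kernel_size, stride
        self.pad = (kernel_size - 1) // 2 if pad is None else pad
        self.dtype = dtype
        fan_in = in_channels * kernel_size * kernel_size
        if zero_init:
            w = np.zeros((out_channels, fan_in))
        else:
            if rng is None:
                rng = np.random.default_rng(0)
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, fan_in))
        self.weight = Param(w, dtype)
        self.bias = Param(np.zeros(out_channels), dtype)
        self._cols_cache = None
        self._pad_shape = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, ho, wo = win.shape[:4]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * k * k
        )
        self._cols_cache, self._pad_shape = cols, xp.shape
        y = cols @ self.weight.value.T + self.bias.value
        return y.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, _, ho, wo = dy.shape
        k, s, p = self.k, self.stride, self.pad
        dy2 = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        cols = self._cols_cache
        self.weight.grad += dy2.T @ cols
        self.bias.grad += dy2.sum(axis=0)
        dcols = (dy2 @ self.weight.value).reshape(n, ho, wo, self.cin, k, k)
        dwin = dcols.transpose(0, 3, 1, 2, 4, 5)  # (n, cin, ho, wo, k, k)
        dxp = np.zeros(self._pad_shape, dtype=dcols.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dwin[:, :, :, :, i, j]
        self._cols_cache = None
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp

    @property
    def n_parameters(self) -> int:
        return self.weight.value.size + self.bias.value.size


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Upsample2x:
    """Nearest-neighbor 2x spatial up-sampling; backward sums 2x2 blocks."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
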