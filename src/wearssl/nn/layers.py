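"""Layers with explicit forward/backward passes.

Each layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients into ``grads`` during ``backward``.
Parameter and gradient arrays are exposed through flat name->array dicts so
optimizers and checkpoints can treat a whole model uniformly.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Layer", "Conv1d", "Dense", "ReLU", "GlobalAvgPool", "Residual", "Sequential"]


class Layer:
    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def zero_grad(self) -> None:
        for g in self.grads().values():
            g[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv1d(Layer):
    """1-D convolution, 'same' padding (k odd), arbitrary stride; He init."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        assert kernel % 2 == 1, "odd kernels only"
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (in_ch * kernel))
        self.W = scale * rng.standard_normal((out_ch, in_ch, kernel))
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.stride = stride
        self.pad = kernel // 2

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._T = x.shape[-1]
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        cols = sliding_window_view(xp, self.W.shape[-1], axis=2)[:, :, ::self.stride, :]
        self._cols = cols
        return np.einsum("nclk,fck->nfl", cols, self.W, optimize=True) + self.b[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW += np.einsum("nfl,nclk->fck", dy, self._cols, optimize=True)
        self.db += dy.sum(axis=(0, 2))
        N, C = self._cols.shape[0], self._cols.shape[1]
        L_out, k = dy.shape[-1], self.W.shape[-1]
        dx_pad = np.zeros((N, C, self._T + 2 * self.pad))
        for kk in range(k):
            dx_pad[:, :, kk:kk + self.stride * L_out:self.stride] += np.einsum(
                "nfl,fc->ncl", dy, self.W[:, :, kk], optimize=True)
        return dx_pad[:, :, self.pad:self.pad + self._T]


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = np.sqrt(2.0 / n_in) * rng.standard_normal((n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW += self._x.T @ dy
        self.db += dy.sum(axis=0)
        return dy @ self.W.T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class GlobalAvgPool(Layer):
    """(N, C, T) -> (N, C) mean over time."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._T = x.shape[-1]
        return x.mean(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, :, None], self._T, axis=2) / self._T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        out = {}
        for i, l in enumerate(self.layers):
            for name, p in l.params().items():
                out[f"{i}.{name}"] = p
        return out

    def grads(self):
        out = {}
        for i, l in enumerate(self.layers):
            for name, g in l.grads().items():
                out[f"{i}.{name}"] = g
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class Residual(Layer):
    """y = ReLU(x + block(x)) with a channel-preserving inner block."""

    def __init__(self, block: Sequential):
        self.block = block

    def params(self):
        return {f"block.{k}": v for k, v in self.block.params().items()}

    def grads(self):
        return {f"block.{k}": v for k, v in self.block.grads().items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.block.forward(x)
        y = x + h
        self._mask = y > 0
        return y * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = dy * self._mask
        return d + self.block.backward(d)
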