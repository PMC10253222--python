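"""Minimal NumPy neural-network engine for volumetric coordinate regression.

Implements exactly the pieces the landmark regressors need — 3D
convolution (same padding, arbitrary stride), ReLU, residual blocks
(basic and bottleneck), global average pooling, flattening, a dense
linear head, mean-squared-error loss and the Adam optimizer — with
hand-written backward passes.  Activations use float32; the convolution
is computed as a windowed tensor contraction (``sliding_window_view`` +
``tensordot``) so the heavy lifting happens in BLAS.

Array layout is (batch, channels, y, x, z) throughout.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ParameterError


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3D(Layer):
    """3D convolution, kernel k, same padding (k//2), stride s."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k**3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k, k))
        self.w = Param(w)
        self.b = Param(np.zeros(cout))
        self.k, self.stride, self.pad = k, stride, k // 2
        self._xp: Optional[np.ndarray] = None

    def params(self):
        return [self.w, self.b]

    def _windows(self, xp: np.ndarray) -> np.ndarray:
        win = sliding_window_view(xp, (self.k, self.k, self.k), axis=(2, 3, 4))
        s = self.stride
        return win[:, :, ::s, ::s, ::s]

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        self._xp = xp
        win = self._windows(xp)  # (B, C, oy, ox, oz, k, k, k)
        y = np.tensordot(win, self.w.value, axes=([1, 5, 6, 7], [1, 2, 3, 4]))
        y = np.ascontiguousarray(np.moveaxis(y, -1, 1))
        y += self.b.value[None, :, None, None, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, s, k, p = self._xp, self.stride, self.k, self.pad
        win = self._windows(xp)
        # (C,k,k,k,O) -> (O,C,k,k,k)
        dw = np.tensordot(win, dy, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
        self.w.grad += np.moveaxis(dw, -1, 0)
        self.b.grad += dy.sum(axis=(0, 2, 3, 4))

        dxp = np.zeros_like(xp)
        oy, ox, oz = dy.shape[2:]
        for i in range(k):
            for j in range(k):
                for m in range(k):
                    contrib = np.tensordot(dy, self.w.value[:, :, i, j, m],
                                           axes=([1], [0]))  # (B,oy,ox,oz,C)
                    dxp[:, :,
                        i : i + s * oy : s,
                        j : j + s * ox : s,
                        m : m + s * oz : s] += np.moveaxis(contrib, -1, 1)
        self._xp = None
        if p:
            return dxp[:, :, p:-p, p:-p, p:-p]
        return dxp


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dy):
        b, c, ny, nx, nz = self._shape
        scale = 1.0 / (ny * nx * nz)
        return np.broadcast_to(
            dy[:, :, None, None, None] * scale, self._shape
        ).astype(np.float32).copy()


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.normal(0.0, np.sqrt(1.0 / nin), size=(nin, nout)))
        self.b = Param(np.zeros(nout))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        dx = dy @ self.w.value.T
        self._x = None
        return dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class ResidualBlock(Layer):
    """y = relu(body(x) + shortcut(x)); shortcut is identity or 1x1 conv."""

    def __init__(self, body: Sequential, shortcut: Optional[Conv3D] = None):
        self.body = body
        self.shortcut = shortcut

    def params(self):
        ps = self.body.params()
        if self.shortcut is not None:
            ps += self.shortcut.params()
        return ps

    def forward(self, x):
        y = self.body.forward(x)
        r = x if self.shortcut is None else self.shortcut.forward(x)
        s = y + r
        self._mask = s > 0
        return np.where(self._mask, s, 0.0)

    def backward(self, dy):
        dy = np.where(self._mask, dy, 0.0)
        dx = self.body.backward(dy)
        if self.shortcut is None:
            dx = dx + dy
        else:
            dx = dx + self.shortcut.backward(dy)
        return dx


def basic_block(cin: int, cout: int, stride: int, rng) -> ResidualBlock:
    body = Sequential([
        Conv3D(cin, cout, 3, stride, rng),
        ReLU(),
        Conv3D(cout, cout, 3, 1, rng),
    ])
    shortcut = None
    if stride != 1 or cin != cout:
        shortcut = Conv3D(cin, cout, 1, stride, rng)
    return ResidualBlock(body, shortcut)


def bottleneck_block(cin: int, cmid: int, stride: int, rng) -> ResidualBlock:
    cout = 4 * cmid
    body = Sequential([
        Conv3D(cin, cmid, 1, stride, rng),
        ReLU(),
        Conv3D(cmid, cmid, 3, 1, rng),
        ReLU(),
        Conv3D(cmid, cout, 1, 1, rng),
    ])
    shortcut = None
    if stride != 1 or cin != cout:
        shortcut = Conv3D(cin, cout, 1, stride, rng)
    return ResidualBlock(body, shortcut)


def out_size(n: int, stride: int) -> int:
    return -(-n // stride)  # ceil division (same padding)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all elements; returns (loss, dL/dpred)."""
    diff = pred - target
    loss = float(np.mean(diff**2))
    grad = (2.0 / diff.size) * diff
    return loss, grad.astype(np.float32)


def check_spatial(shape: tuple[int, int, int], n_halvings: int) -> None:
    """Raise if the downsampling chain would collapse a spatial dim."""
    if min(shape) < 2**n_halvings:
        raise ParameterError(
            f"input shape {shape} is too small for {n_halvings} stride-2 stages"
        )
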