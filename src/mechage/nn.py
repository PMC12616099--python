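"""A compact, self-contained 3D conv-net toolkit on numpy.

Implements exactly the pieces the brain-age encoders need: 3D convolution
(im2col-based) with stride and padding, ReLU, global average pooling, fully
connected layers, residual blocks, He initialisation, and Adam. Forward and
backward passes are written by hand and covered by finite-difference
gradient checks in the test suite. Everything is deterministic given the
initialisation seed; there are no stochastic layers.

Volumes are small (8-32 voxels per side), so plain numpy matmuls are fast
enough for desk-scale training on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Param", "Layer", "Conv3d", "ReLU", "GlobalAvgPool", "Linear",
           "ResidualBlock3d", "Sequential", "Adam", "build_small_cnn",
           "build_resnet3d", "l2_normalize"]


@dataclass
class Param:
    value: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3d(Layer):
    """k^3 convolution with symmetric zero padding.

    Input (B, C, X, Y, Z) -> output (B, O, X', Y', Z') with
    X' = floor((X + 2p - k) / s) + 1.
    """

    def __init__(self, in_c: int, out_c: int, k: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None):
        self.in_c, self.out_c, self.k, self.stride, self.pad = in_c, out_c, k, stride, pad
        rng = rng or np.random.default_rng(0)
        fan_in = in_c * k ** 3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, out_c))
        self.W = Param(w)
        self.b = Param(np.zeros(out_c))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _out_shape(self, d: int) -> int:
        return (d + 2 * self.pad - self.k) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        B, C = x.shape[:2]
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        win = win[:, :, ::s, ::s, ::s]  # (B, C, Xo, Yo, Zo, k, k, k)
        Xo, Yo, Zo = win.shape[2:5]
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(B, Xo * Yo * Zo, C * k ** 3)
        out = cols @ self.W.value + self.b.value
        self._cache = (cols, x.shape, (Xo, Yo, Zo))
        return out.transpose(0, 2, 1).reshape(B, self.out_c, Xo, Yo, Zo)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, xshape, (Xo, Yo, Zo) = self._cache
        k, s, p = self.k, self.stride, self.pad
        B, C = xshape[:2]
        g = grad.reshape(B, self.out_c, -1).transpose(0, 2, 1)  # (B, P, O)
        self.W.grad += np.einsum("bpc,bpo->co", cols, g)
        self.b.grad += g.sum(axis=(0, 1))
        dcols = g @ self.W.value.T  # (B, P, C*k^3)
        dcols = dcols.reshape(B, Xo, Yo, Zo, C, k, k, k)
        dxp = np.zeros((B, C, xshape[2] + 2 * p, xshape[3] + 2 * p, xshape[4] + 2 * p))
        for a in range(k):
            for bb in range(k):
                for c in range(k):
                    dxp[:, :,
                        a:a + s * Xo:s,
                        bb:bb + s * Yo:s,
                        c:c + s * Zo:s] += dcols[:, :, :, :, :, a, bb, c].transpose(0, 4, 1, 2, 3)
        if p:
            return dxp[:, :, p:-p, p:-p, p:-p]
        return dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class GlobalAvgPool(Layer):
    """(B, C, X, Y, Z) -> (B, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, X, Y, Z = self._shape
        scale = 1.0 / (X * Y * Z)
        return np.broadcast_to(grad[:, :, None, None, None],
                               self._shape).copy() * scale


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / in_f), size=(in_f, out_f)))
        self.b = Param(np.zeros(out_f))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class ResidualBlock3d(Layer):
    """Two 3x3x3 convs with identity (or 1x1x1 strided projection) skip."""

    def __init__(self, in_c: int, out_c: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        self.conv1 = Conv3d(in_c, out_c, 3, stride, 1, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(out_c, out_c, 3, 1, 1, rng)
        self.proj = None
        if stride != 1 or in_c != out_c:
            self.proj = Conv3d(in_c, out_c, 1, stride, 0, rng)
        self.relu2 = ReLU()

    def params(self) -> list[Param]:
        ps = self.conv1.params() + self.conv2.params()
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        sk = x if self.proj is None else self.proj.forward(x)
        return self.relu2.forward(h + sk)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.relu2.backward(grad)
        gx_skip = g if self.proj is None else self.proj.backward(g)
        gx_main = self.conv1.backward(self.relu1.backward(self.conv2.backward(g)))
        return gx_main + gx_skip


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        ps = self.params()
        if len(ps) != len(state):
            raise ValueError("state length mismatch")
        for p, v in zip(ps, state):
            if p.value.shape != v.shape:
                raise ValueError("state shape mismatch")
            p.value[...] = v


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def build_small_cnn(in_channels: int, embedding_dim: int,
                    width_multiplier: int = 1,
                    rng: np.random.Generator | None = None) -> Sequential:
    """Three stride-2 conv blocks, global average pool, linear projection."""
    rng = rng or np.random.default_rng(0)
    w = 8 * width_multiplier
    return Sequential([
        Conv3d(in_channels, w, 3, 2, 1, rng), ReLU(),
        Conv3d(w, 2 * w, 3, 2, 1, rng), ReLU(),
        Conv3d(2 * w, 4 * w, 3, 2, 1, rng), ReLU(),
        GlobalAvgPool(),
        Linear(4 * w, embedding_dim, rng),
    ])


def build_resnet3d(in_channels: int, embedding_dim: int,
                   width_multiplier: int = 1,
                   rng: np.random.Generator | None = None) -> Sequential:
    """A slim ResNet-18-style 3D backbone: stem + three residual stages."""
    rng = rng or np.random.default_rng(0)
    w = 8 * width_multiplier
    return Sequential([
        Conv3d(in_channels, w, 3, 1, 1, rng), ReLU(),
        ResidualBlock3d(w, w, 2, rng),
        ResidualBlock3d(w, 2 * w, 2, rng),
        ResidualBlock3d(2 * w, 4 * w, 2, rng),
        GlobalAvgPool(),
        Linear(4 * w, embedding_dim, rng),
    ])


def l2_normalize(X: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Row-normalise to unit Euclidean length."""
    return X / np.maximum(np.linalg.norm(X, axis=1, keepdims=True), eps)
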