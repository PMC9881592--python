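"""Minimal CPU neural-network engine: layers with explicit backprop and Adam.

Sized for the small convolutional/dense models this package trains (64x64
images, latent dimensions in the tens). Every layer implements ``forward``
(caching what backward needs) and ``backward`` (returning the gradient with
respect to its input and accumulating parameter gradients). Correctness is
pinned by finite-difference gradient checks and a scipy convolution oracle in
the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Dense",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "Flatten",
    "Reshape",
    "UpsampleNearest2",
    "Sequential",
    "Adam",
]


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, gy):
        self.W.grad += self._x.T @ gy
        self.b.grad += gy.sum(axis=0)
        return gy @ self.W.value.T


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*k*k, Ho*Wo) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, k, k, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    return np.ascontiguousarray(cols).reshape(n, c * k * k, ho * wo), (ho, wo)


def _col2im(
    gcols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int
) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back to image layout."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    g = gcols.reshape(n, c, k, k, ho, wo)
    gx = np.zeros((n, c, hp, wp))
    for i in range(k):
        for j in range(k):
            gx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += g[
                :, :, i, j, :, :
            ]
    if pad:
        gx = gx[:, :, pad : pad + h, pad : pad + w]
    return gx


class Conv2d(Layer):
    """2D cross-correlation via im2col; He-initialized."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        k: int = 3,
        stride: int = 1,
        pad: int = 1,
        rng: np.random.Generator | None = None,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = in_ch * k * k
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in)))
        self.b = Param(np.zeros(out_ch))
        self.k, self.stride, self.pad = k, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch
        self._cols: np.ndarray | None = None
        self._x_shape: tuple | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.shape[1]}")
        cols, (ho, wo) = _im2col(x, self.k, self.stride, self.pad)
        self._cols, self._x_shape = cols, x.shape
        y = np.einsum("of,nfl->nol", self.W.value, cols, optimize=True)
        y += self.b.value[None, :, None]
        return y.reshape(x.shape[0], self.out_ch, ho, wo)

    def backward(self, gy):
        n = gy.shape[0]
        g = gy.reshape(n, self.out_ch, -1)
        self.W.grad += np.einsum("nol,nfl->of", g, self._cols, optimize=True)
        self.b.grad += g.sum(axis=(0, 2))
        gcols = np.einsum("of,nol->nfl", self.W.value, g, optimize=True)
        return _col2im(gcols, self._x_shape, self.k, self.stride, self.pad)


class BatchNorm2d(Layer):
    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_ch))
        self.beta = Param(np.zeros(n_ch))
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * ivar[None, :, None, None]
        self._cache = (xhat, ivar, train, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, gy):
        xhat, ivar, train, shape = self._cache
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        gxhat = gy * self.gamma.value[None, :, None, None]
        if not train:
            return gxhat * ivar[None, :, None, None]
        m = shape[0] * shape[2] * shape[3]
        sum_g = gxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_gx = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (
            ivar[None, :, None, None] / m * (m * gxhat - sum_g - xhat * sum_gx)
        )


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=True):
        out = np.empty_like(x, dtype=float)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        e = np.exp(x[~pos])
        out[~pos] = e / (1.0 + e)
        self._y = out
        return out

    def backward(self, gy):
        return gy * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple):
        self.shape = shape  # per-sample shape

    def forward(self, x, train=True):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], *self.shape)

    def backward(self, gy):
        return gy.reshape(self._in_shape)


class UpsampleNearest2(Layer):
    """2x nearest-neighbor spatial upsampling."""

    def forward(self, x, train=True):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy):
        n, c, h, w = gy.shape
        return gy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.beta1) * (p.grad - m)
            v += (1.0 - self.beta2) * (p.grad**2 - v)
            p.value -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def n_params(layer: Layer) -> int:
    """Total number of scalar trainable parameters in a layer/model."""
    return int(sum(p.value.size for p in layer.params()))
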