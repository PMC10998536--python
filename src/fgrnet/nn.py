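"""Minimal numpy neural-network core: layers with explicit backprop and Adam.

All tensors are float64.  Convolutional layers use the (batch, channels,
length) layout.  Layers cache whatever the backward pass needs on ``self``,
so a ``backward`` call must follow the ``forward`` call it differentiates.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param", "Layer", "Dense", "Conv1d", "BatchNorm1d", "ReLU", "LeakyReLU",
    "Sigmoid", "MaxPool1d", "GlobalAvgPool1d", "Upsample1d", "Flatten",
    "Dropout", "Sequential", "Adam", "softmax",
]


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    """Affine map on (N, F) inputs."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator) -> None:
        scale = np.sqrt(2.0 / (in_dim + out_dim))
        self.w = Param(rng.normal(0.0, scale, size=(in_dim, out_dim)), "dense.w")
        self.b = Param(np.zeros(out_dim), "dense.b")

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class Conv1d(Layer):
    """1-D convolution with "same" padding (odd kernels only)."""

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int,
                 rng: np.random.Generator) -> None:
        if kernel_size < 1 or kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be a positive odd integer, got {kernel_size}")
        scale = np.sqrt(2.0 / (in_ch * kernel_size))
        self.w = Param(rng.normal(0.0, scale, size=(out_ch, in_ch, kernel_size)), "conv.w")
        self.b = Param(np.zeros(out_ch), "conv.b")
        self.k = kernel_size

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        n, c, length = x.shape
        pad = (self.k - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        # cols[n, c, l, k] = xp[n, c, l + k]; flattened to (n*l, c*k) for BLAS
        cols = sliding_window_view(xp, self.k, axis=2)
        cols2d = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(n * length, c * self.k)
        self._cols2d = cols2d
        self._in_shape = x.shape
        o = self.w.value.shape[0]
        y = cols2d @ self.w.value.reshape(o, c * self.k).T
        y = y.reshape(n, length, o).transpose(0, 2, 1)
        return y + self.b.value[None, :, None]

    def backward(self, dy):
        n, c, length = self._in_shape
        pad = (self.k - 1) // 2
        o = self.w.value.shape[0]
        dy2d = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(n * length, o)
        self.w.grad += (dy2d.T @ self._cols2d).reshape(o, c, self.k)
        self.b.grad += dy2d.sum(axis=0)
        dcols = (dy2d @ self.w.value.reshape(o, c * self.k)).reshape(n, length, c, self.k)
        dxp = np.zeros((n, c, length + 2 * pad))
        for k in range(self.k):
            dxp[:, :, k:k + length] += dcols[:, :, :, k].transpose(0, 2, 1)
        return dxp[:, :, pad:pad + length] if pad else dxp


class BatchNorm1d(Layer):
    """Per-channel batch normalization on (N, C) or (N, C, L) inputs."""

    def __init__(self, n_ch: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(n_ch), "bn.gamma")
        self.beta = Param(np.zeros(n_ch), "bn.beta")
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def _shape(self, x):
        if x.ndim == 2:
            return (0,), self.gamma.value[None, :], self.beta.value[None, :]
        return (0, 2), self.gamma.value[None, :, None], self.beta.value[None, :, None]

    def forward(self, x, training=False):
        axes, g, b = self._shape(x)
        self._training = training
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        if x.ndim == 3:
            mean = mean[None, :, None]
            var = var[None, :, None]
        else:
            mean = mean[None, :]
            var = var[None, :]
        self._invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._invstd
        self._axes = axes
        return g * self._xhat + b

    def backward(self, dy):
        axes, g, _ = self._shape(dy)
        xhat = self._xhat
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * g
        if not self._training:
            return dxhat * self._invstd
        m = dy.size / dy.shape[1]
        keep = {"keepdims": True}
        term = dxhat - dxhat.sum(axis=axes, **keep) / m \
            - xhat * (dxhat * xhat).sum(axis=axes, **keep) / m
        return term * self._invstd


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2) -> None:
        self.alpha = alpha

    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.alpha * dy)


class Sigmoid(Layer):
    def forward(self, x, training=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class MaxPool1d(Layer):
    """Max pooling with ceil-mode right padding, so any length survives."""

    def __init__(self, pool_size: int) -> None:
        if pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        self.p = pool_size

    def forward(self, x, training=False):
        if self.p == 1:
            self._identity = True
            return x
        self._identity = False
        n, c, length = x.shape
        out_len = -(-length // self.p)
        pad = out_len * self.p - length
        xp = np.pad(x, ((0, 0), (0, 0), (0, pad)), constant_values=-np.inf)
        xw = xp.reshape(n, c, out_len, self.p)
        self._arg = xw.argmax(axis=3)
        self._in_len = length
        self._pad = pad
        return np.take_along_axis(xw, self._arg[..., None], axis=3)[..., 0]

    def backward(self, dy):
        if self._identity:
            return dy
        n, c, out_len = dy.shape
        dxw = np.zeros((n, c, out_len, self.p))
        np.put_along_axis(dxw, self._arg[..., None], dy[..., None], axis=3)
        dxp = dxw.reshape(n, c, out_len * self.p)
        return dxp[:, :, : self._in_len]


class GlobalAvgPool1d(Layer):
    def forward(self, x, training=False):
        self._len = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy):
        return np.repeat(dy[:, :, None], self._len, axis=2) / self._len


class Upsample1d(Layer):
    """Nearest-neighbour upsampling along the length axis."""

    def __init__(self, factor: int = 2) -> None:
        self.f = factor

    def forward(self, x, training=False):
        return np.repeat(x, self.f, axis=2)

    def backward(self, dy):
        n, c, length = dy.shape
        return dy.reshape(n, c, length // self.f, self.f).sum(axis=3)


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        if not 0.0 <= rate <= 1.0:
            raise ValueError("dropout rate must be in [0, 1]")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if self.rate == 1.0:
            self._mask = np.zeros_like(x)
            return self._mask
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        if self.rate == 1.0:
            return np.zeros_like(dy)
        return dy * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def params(self):
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adam optimizer over a flat list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax of a (N, C) logit matrix."""
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def get_state(params: list[Param]) -> list[np.ndarray]:
    return [p.value.copy() for p in params]


def set_state(params: list[Param], state: list[np.ndarray]) -> None:
    for p, s in zip(params, state, strict=True):
        p.value[...] = s
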