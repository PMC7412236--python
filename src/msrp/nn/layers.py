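"""Minimal NumPy layers for 2-D convolutional classifiers.

All layers operate on float32 NCHW batches and implement ``forward`` /
``backward`` with cached activations, exposing flat lists of parameter and
gradient arrays for the optimizer.  Convolutions use "same" zero padding
(stride 1) via an im2col view so the heavy lifting is a single BLAS matmul
per layer.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "BatchNorm2D",
    "ReLU",
    "MaxPool2x2",
    "GlobalAvgPool",
    "Flatten",
    "Dense",
    "Add",
]


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (C*k*k, N*H*W) patch matrix under same-padding."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    # windows: (N, C, H, W, k, k)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    cols = win.transpose(1, 4, 5, 0, 2, 3).reshape(c * k * k, n * h * w)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int, int], k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back to the image."""
    n, c, h, w = shape
    p = k // 2
    dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dcols.dtype)
    d = dcols.reshape(c, k, k, n, h, w)
    for di in range(k):
        for dj in range(k):
            dxp[:, :, di:di + h, dj:dj + w] += d[:, di, dj].transpose(1, 0, 2, 3)
    return dxp[:, :, p:p + h, p:p + w]


class Conv2D(Layer):
    """k x k convolution, stride 1, same padding, He-initialized."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.W = (rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, int, int, int] | None = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=True):
        self._xshape = x.shape
        cols = _im2col(x, self.k)
        self._cols = cols if train else None
        n, _, h, w = x.shape
        out = self.W @ cols + self.b[:, None]
        return out.reshape(self.c_out, n, h, w).transpose(1, 0, 2, 3)

    def backward(self, dout):
        n, _, h, w = self._xshape
        dmat = dout.transpose(1, 0, 2, 3).reshape(self.c_out, n * h * w)
        self.dW[...] = dmat @ self._cols.T
        self.db[...] = dmat.sum(axis=1)
        dcols = self.W.T @ dmat
        self._cols = None
        return _col2im(dcols, self._xshape, self.k)


class BatchNorm2D(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._xhat, self._inv = xhat, inv
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout):
        xhat, inv = self._xhat, self._inv
        n_eff = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma[...] = (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dout.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None] * inv[None, :, None, None]
        dx = g * (dout
                  - (self.dbeta / n_eff)[None, :, None, None]
                  - xhat * (self.dgamma / n_eff)[None, :, None, None])
        self._xhat = None
        return dx


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2x2(Layer):
    """2x2 max pooling with stride 2 (odd trailing rows/columns dropped)."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        self._xshape = x.shape
        xc = x[:, :, :h2 * 2, :w2 * 2].reshape(n, c, h2, 2, w2, 2)
        out = xc.max(axis=(3, 5))
        self._mask = xc == out[:, :, :, None, :, None]
        return out

    def backward(self, dout):
        n, c, h, w = self._xshape
        h2, w2 = h // 2, w // 2
        dx = np.zeros(self._xshape, dtype=dout.dtype)
        dpatch = self._mask * dout[:, :, :, None, :, None]
        dx[:, :, :h2 * 2, :w2 * 2] = dpatch.reshape(n, c, h2 * 2, w2 * 2)
        return dx


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x, train=True):
        self._xshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._xshape
        return np.broadcast_to(dout[:, :, None, None] / (h * w), self._xshape).astype(dout.dtype)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._xshape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        self._x = None
        return dout @ self.W.T


class Add(Layer):
    """Residual addition of the main path and a (possibly projected) shortcut."""

    def __init__(self, main: list[Layer], shortcut: list[Layer]):
        self.main = main
        self.shortcut = shortcut

    def params(self):
        return [p for lay in (*self.main, *self.shortcut) for p in lay.params()]

    def grads(self):
        return [g for lay in (*self.main, *self.shortcut) for g in lay.grads()]

    def forward(self, x, train=True):
        a = x
        for lay in self.main:
            a = lay.forward(a, train)
        s = x
        for lay in self.shortcut:
            s = lay.forward(s, train)
        return a + s

    def backward(self, dout):
        da = dout
        for lay in reversed(self.main):
            da = lay.backward(da)
        ds = dout
        for lay in reversed(self.shortcut):
            ds = lay.backward(ds)
        return da + ds


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
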