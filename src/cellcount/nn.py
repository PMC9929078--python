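"""A minimal CNN engine on numpy: the layers, loss and optimizer the count
regressor needs, and nothing else.

Layout is NHWC float32 throughout.  Convolutions are 'valid' with stride 1,
computed by gathering 3x3 (or kxk) patches with ``sliding_window_view`` and a
single BLAS matmul per layer; the input gradient is accumulated as one matmul
per kernel offset, which keeps the backward pass allocation-free apart from
the output buffers.  Max-pooling is 2x2 stride 2 (floor; trailing odd
rows/columns are dropped, matching 'valid' pooling).  Dropout is inverted
(activations scaled by 1/(1-p) at train time) so inference needs no rescaling.

This is deliberately small: a handful of layer classes, MSE loss, and Adam.
Determinism: all randomness (init, shuffling, dropout masks) flows from
numpy Generators supplied by the caller.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2D", "MaxPool2", "Flatten", "Dropout", "Dense", "Sequential", "Adam"]


class Layer:
    """Base: stateless unless it owns parameters (then ``params``/``grads``)."""

    def params(self) -> list:
        return []

    def grads(self) -> list:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """k x k valid convolution, stride 1, with ReLU folded in."""

    def __init__(self, in_ch: int, filters: int, kernel: int,
                 rng: np.random.Generator, relu: bool = True):
        fan_in = kernel * kernel * in_ch
        scale = np.sqrt(2.0 / fan_in)
        self.W = (rng.standard_normal((kernel, kernel, in_ch, filters))
                  * scale).astype(np.float32)
        self.b = np.zeros(filters, dtype=np.float32)
        self.k = kernel
        self.relu = relu
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train):
        k = self.k
        n, h, w, c = x.shape
        oh, ow = h - k + 1, w - k + 1
        patches = sliding_window_view(x, (k, k), axis=(1, 2))  # (n,oh,ow,c,k,k)
        patches = patches.transpose(0, 1, 2, 4, 5, 3).reshape(n * oh * ow, k * k * c)
        out = patches @ self.W.reshape(k * k * c, -1) + self.b
        out = out.reshape(n, oh, ow, -1)
        if train:
            self._patches = patches
            self._xshape = x.shape
        pre = out
        if self.relu:
            out = np.maximum(out, 0.0)
        if train:
            self._mask = pre > 0 if self.relu else None
        return out

    def backward(self, dout):
        if self.relu:
            dout = dout * self._mask
        k = self.k
        n, oh, ow, f = dout.shape
        _, h, w, c = self._xshape
        dflat = dout.reshape(-1, f)
        self.dW[...] = (self._patches.T @ dflat).reshape(self.W.shape)
        self.db[...] = dflat.sum(axis=0)
        dx = np.zeros(self._xshape, dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                # contribution of kernel offset (di, dj) to the input gradient
                dx[:, di:di + oh, dj:dj + ow, :] += dout @ self.W[di, dj].T
        self._patches = None
        return dx


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x, train):
        n, h, w, c = x.shape
        oh, ow = h // 2, w // 2
        xc = x[:, :2 * oh, :2 * ow, :]
        windows = xc.reshape(n, oh, 2, ow, 2, c)
        out = windows.max(axis=(2, 4))
        if train:
            self._windows_shape = windows.shape
            self._xshape = x.shape
            self._mask = windows == out[:, :, None, :, None, :]
        return out

    def backward(self, dout):
        mask = self._mask
        counts = mask.sum(axis=(2, 4), keepdims=True)  # ties share the gradient
        d = mask * (dout[:, :, None, :, None, :] / counts)
        n, h, w, c = self._xshape
        oh, ow = h // 2, w // 2
        dx = np.zeros(self._xshape, dtype=np.float32)
        dx[:, :2 * oh, :2 * ow, :] = d.reshape(n, 2 * oh, 2 * ow, c)
        self._mask = None
        return dx


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity when rate is 0 or at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Dense(Layer):
    """Fully connected layer, optional ReLU; bias initialisable away from zero
    so a ReLU output unit starts alive."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 relu: bool = False, bias_init: float = 0.0):
        scale = np.sqrt(2.0 / in_dim)
        self.W = (rng.standard_normal((in_dim, out_dim)) * scale).astype(np.float32)
        self.b = np.full(out_dim, bias_init, dtype=np.float32)
        self.relu = relu
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train):
        pre = x @ self.W + self.b
        if train:
            self._x = x
        out = np.maximum(pre, 0.0) if self.relu else pre
        if train:
            self._mask = pre > 0 if self.relu else None
        return out

    def backward(self, dout):
        if self.relu:
            dout = dout * self._mask
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx


class Sequential:
    """An ordered stack of layers with forward/backward and weight snapshots."""

    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self) -> list:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list:
        return [g for layer in self.layers for g in layer.grads()]

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))

    def get_weights(self) -> list:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p[...] = w


class Adam:
    """Adam with bias correction; operates in place on a Sequential's params."""

    def __init__(self, model: Sequential, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 clipnorm: float | None = None):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.clipnorm = clipnorm
        self.m = [np.zeros_like(p) for p in model.params()]
        self.v = [np.zeros_like(p) for p in model.params()]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        grads = self.model.grads()
        if self.clipnorm is not None:
            # global-norm clipping tames the large early steps that can push
            # the ReLU output unit permanently below zero
            norm = np.sqrt(sum(float((g * g).sum()) for g in grads))
            if norm > self.clipnorm:
                scale = self.clipnorm / norm
                for g in grads:
                    g *= scale
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for p, g, m, v in zip(self.model.params(), grads,
                              self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)
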