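"""Minimal NHWC convolutional layers with manual backpropagation.

The autoencoder in this package is deliberately shallow (two convolutional
layers on 3x3 patches), so the handful of layers it needs — 1x1 and kxk
valid convolutions, their transposed counterparts, batch normalization,
ReLU/sigmoid, and an Adam optimizer — are implemented directly on numpy
arrays.  All tensors are (batch, height, width, channels); gradients are
exact and covered by numerical gradient-check tests.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer: ``params``/``grads`` are parallel lists of arrays."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, fan_in: int, shape: tuple) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Conv1x1(Layer):
    """Pointwise convolution: a dense map applied at every pixel."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = _he_init(rng, c_in, (c_in, c_out))
        self.b = np.zeros(c_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, training):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        x = self._x
        self.grads[0][...] = np.tensordot(x, grad, axes=([0, 1, 2], [0, 1, 2]))
        self.grads[1][...] = grad.sum(axis=(0, 1, 2))
        return grad @ self.w.T


class ConvValid(Layer):
    """k x k valid convolution, stride 1 (im2col implementation)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.k = k
        self.w = _he_init(rng, k * k * c_in, (k * k * c_in, c_out))
        self.b = np.zeros(c_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def _im2col(self, x):
        n, h, w, c = x.shape
        k = self.k
        oh, ow = h - k + 1, w - k + 1
        cols = np.empty((n, oh, ow, k, k, c), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, :, i, j, :] = x[:, i : i + oh, j : j + ow, :]
        return cols.reshape(n, oh, ow, k * k * c)

    def forward(self, x, training):
        self._xshape = x.shape
        self._cols = self._im2col(x)
        return self._cols @ self.w + self.b

    def backward(self, grad):
        n, h, w, c = self._xshape
        k = self.k
        oh, ow = h - k + 1, w - k + 1
        self.grads[0][...] = np.tensordot(self._cols, grad, axes=([0, 1, 2], [0, 1, 2]))
        self.grads[1][...] = grad.sum(axis=(0, 1, 2))
        gcols = (grad @ self.w.T).reshape(n, oh, ow, k, k, c)
        gx = np.zeros(self._xshape, dtype=grad.dtype)
        for i in range(k):
            for j in range(k):
                gx[:, i : i + oh, j : j + ow, :] += gcols[:, :, :, i, j, :]
        return gx


class ConvTranspose(Layer):
    """Transposed k x k convolution, stride 1 (spatially enlarging)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.k = k
        self.w = _he_init(rng, c_in, (k, k, c_in, c_out))
        self.b = np.zeros(c_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, training):
        self._x = x
        n, h, w, c = x.shape
        k = self.k
        y = np.zeros((n, h + k - 1, w + k - 1, self.b.size), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                y[:, i : i + h, j : j + w, :] += x @ self.w[i, j]
        return y + self.b

    def backward(self, grad):
        x = self._x
        n, h, w, c = x.shape
        k = self.k
        gx = np.zeros_like(x)
        for i in range(k):
            for j in range(k):
                g = grad[:, i : i + h, j : j + w, :]
                self.grads[0][i, j] = np.tensordot(x, g, axes=([0, 1, 2], [0, 1, 2]))
                gx += g @ self.w[i, j].T
        self.grads[1][...] = grad.sum(axis=(0, 1, 2))
        return gx


class BatchNorm(Layer):
    """Per-channel batch normalization over (batch, height, width)."""

    def __init__(self, c: int, momentum: float = 0.99, eps: float = 1e-3):
        super().__init__()
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training):
        if training:
            axes = (0, 1, 2)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._m = x.shape[0] * x.shape[1] * x.shape[2]
            self._xhat = (x - mean) / np.sqrt(var + self.eps)
            self._istd = 1.0 / np.sqrt(var + self.eps)
            return self.gamma * self._xhat + self.beta
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.gamma * xhat + self.beta

    def backward(self, grad):
        xhat, istd, m = self._xhat, self._istd, self._m
        self.grads[0][...] = (grad * xhat).sum(axis=(0, 1, 2))
        self.grads[1][...] = grad.sum(axis=(0, 1, 2))
        gxhat = grad * self.gamma
        return (
            istd
            / m
            * (
                m * gxhat
                - gxhat.sum(axis=(0, 1, 2))
                - xhat * (gxhat * xhat).sum(axis=(0, 1, 2))
            )
        )


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x, training):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adam stochastic gradient optimizer."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
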