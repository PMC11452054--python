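"""Minimal neural-network building blocks in numpy (float32).

Only what the convolutional VAE needs: 1-D convolutions (stride 1 or 2,
'same'-style padding, kernel 3 by default), transposed convolutions built
from zero-stuffing plus a stride-1 convolution, dense layers, tanh, and an
Adam optimizer. Forward passes cache what the analytic backward passes need;
gradients were validated against finite differences in the test suite.

Array convention: signals are (batch, length, channels).
"""

from __future__ import annotations

from typing import List

import numpy as np

DTYPE = np.float32


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)


def glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Layer:
    def parameters(self) -> List[Parameter]:
        return []


class Conv1d(Layer):
    """1-D convolution, kernel ``k``, stride 1 or 2, zero padding (k-1)/2."""

    def __init__(self, rng, c_in: int, c_out: int, k: int = 3, stride: int = 1):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = (k - 1) // 2
        self.W = Parameter(glorot(rng, (k * c_in, c_out), k * c_in, c_out))
        self.b = Parameter(np.zeros(c_out, dtype=DTYPE))
        self._cols = None
        self._in_shape = None

    def parameters(self):
        return [self.W, self.b]

    def _l_out(self, l_in: int) -> int:
        return l_in if self.stride == 1 else l_in // 2

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, l_in, _ = x.shape
        l_out = self._l_out(l_in)
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)))
        taps = [xp[:, j:j + self.stride * (l_out - 1) + 1:self.stride, :]
                for j in range(self.k)]
        cols = np.concatenate(taps, axis=2)  # (n, l_out, k*c_in)
        self._cols, self._in_shape = cols, x.shape
        return cols @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, l_in, _ = self._in_shape
        l_out = dy.shape[1]
        cols2 = self._cols.reshape(-1, self.k * self.c_in)
        dy2 = dy.reshape(-1, self.c_out)
        self.W.grad += cols2.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        dcols = dy @ self.W.value.T  # (n, l_out, k*c_in)
        dxp = np.zeros((n, l_in + 2 * self.pad, self.c_in), dtype=DTYPE)
        for j in range(self.k):
            dxp[:, j:j + self.stride * (l_out - 1) + 1:self.stride, :] += \
                dcols[:, :, j * self.c_in:(j + 1) * self.c_in]
        return dxp[:, self.pad:self.pad + l_in, :]


class ConvTranspose1d(Layer):
    """Stride-2 transposed convolution: zero-stuff then stride-1 convolve."""

    def __init__(self, rng, c_in: int, c_out: int, k: int = 3):
        self.conv = Conv1d(rng, c_in, c_out, k=k, stride=1)
        self.c_in, self.c_out = c_in, c_out

    def parameters(self):
        return self.conv.parameters()

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, l_in, c = x.shape
        up = np.zeros((n, 2 * l_in, c), dtype=DTYPE)
        up[:, ::2, :] = x
        return self.conv.forward(up)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dup = self.conv.backward(dy)
        return dup[:, ::2, :]


class Dense(Layer):
    def __init__(self, rng, d_in: int, d_out: int):
        self.W = Parameter(glorot(rng, (d_in, d_out), d_in, d_out))
        self.b = Parameter(np.zeros(d_out, dtype=DTYPE))
        self._x = None

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.reshape(-1, self._x.shape[-1]).T @ dy.reshape(-1, dy.shape[-1])
        self.b.grad += dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        return dy @ self.W.value.T


class Tanh(Layer):
    def __init__(self):
        self._y = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * (1.0 - self._y ** 2)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class Adam:
    def __init__(self, params: List[Parameter], lr: float = 1e-3,
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
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def get_weights(layers: Layer) -> List[np.ndarray]:
    return [p.value.copy() for p in layers.parameters()]


def set_weights(layers: Layer, weights: List[np.ndarray]) -> None:
    for p, w in zip(layers.parameters(), weights):
        p.value[...] = w
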