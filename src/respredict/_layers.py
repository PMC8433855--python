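"""Minimal NumPy layer primitives with hand-written backpropagation.

Sequences are arrays of shape (batch, time, channels). Each layer caches
what its backward pass needs during forward; backward accumulates parameter
gradients in place and returns the gradient with respect to its input.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError


class Param:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class CausalConv1d:
    """Dilated causal convolution: y[t] = b + sum_i W[i] . x[t - i*d].

    Left zero-padding of (k-1)*d keeps the output length equal to the input
    length; the output at time t never reads inputs later than t.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int, dilation: int,
                 rng: np.random.Generator, name: str = "conv"):
        if kernel_size < 1 or dilation < 1:
            raise ConfigurationError("kernel_size and dilation must be >= 1")
        self.c_in, self.c_out, self.k, self.d = c_in, c_out, kernel_size, dilation
        scale = 1.0 / np.sqrt(kernel_size * c_in)
        self.W = Param(f"{name}.W", rng.normal(0.0, scale, size=(kernel_size, c_in, c_out)))
        self.b = Param(f"{name}.b", np.zeros(c_out))
        self._xp: np.ndarray | None = None

    @property
    def pad(self) -> int:
        return (self.k - 1) * self.d

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, _ = x.shape
        if T < 1:
            raise ConfigurationError("empty input sequence")
        P = self.pad
        xp = np.pad(x, ((0, 0), (P, 0), (0, 0)))
        y = np.tile(self.b.value, (B, T, 1))
        for i in range(self.k):
            start = P - i * self.d
            y += xp[:, start:start + T, :] @ self.W.value[i]
        self._xp = xp
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        B, T, _ = dy.shape
        P = self.pad
        dxp = np.zeros_like(xp)
        dy2 = dy.reshape(-1, dy.shape[-1])
        for i in range(self.k):
            start = P - i * self.d
            sl = xp[:, start:start + T, :]
            self.W.grad[i] += sl.reshape(-1, sl.shape[-1]).T @ dy2
            dxp[:, start:start + T, :] += dy @ self.W.value[i].T
        self.b.grad += dy2.sum(axis=0)
        return dxp[:, P:, :]


class ReLU:
    def params(self):
        return []

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class Identity:
    def params(self):
        return []

    def forward(self, x, train=False):
        return x

    def backward(self, dy):
        return dy


def make_activation(name: str):
    if name == "relu":
        return ReLU()
    if name == "identity":
        return Identity()
    raise ConfigurationError(f"unknown activation {name!r} (expected 'relu' or 'identity')")


class Dropout:
    """Inverted dropout; a no-op at rate 0 or in inference mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ConfigurationError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def params(self):
        return []

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Linear:
    """Affine map applied to the last axis."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, name: str = "linear"):
        self.W = Param(f"{name}.W", rng.normal(0.0, 1.0 / np.sqrt(c_in), size=(c_in, c_out)))
        self.b = Param(f"{name}.b", np.zeros(c_out))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.W.grad += x2.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        return dy @ self.W.value.T
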