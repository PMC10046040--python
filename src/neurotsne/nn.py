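"""Minimal feed-forward layers with reverse-mode gradients, in numpy.

Layers cache what their backward pass needs during ``forward`` and release
gradients through ``backward``; parameters and their gradients live on the
layer.  Convolutions are 1-D with 'same' zero padding and are lowered to a
single BLAS matmul via an im2col view, which is what makes CPU training of
the encoders practical.  Gradients of every layer are verified against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    __slots__ = ("value", "grad", "regularized")

    def __init__(self, value: np.ndarray, regularized: bool = True):
        self.value = value
        self.grad = np.zeros_like(value)
        self.regularized = regularized


def variance_scaling_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """Uniform variance-scaling initialization (Glorot-style on fan-in)."""
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    """Affine map on the last axis: (N, D) -> (N, M)."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = Parameter(variance_scaling_init(rng, (in_dim, out_dim), in_dim))
        self.b = Parameter(np.zeros(out_dim), regularized=False)

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class Conv1d(Layer):
    """1-D convolution with 'same' zero padding: (N, Cin, T) -> (N, Cout, T).

    Requires an odd kernel size so 'same' padding is symmetric.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for symmetric 'same' padding")
        self.kernel = kernel
        self.in_ch = in_ch
        self.out_ch = out_ch
        fan_in = in_ch * kernel
        self.W = Parameter(variance_scaling_init(rng, (in_ch * kernel, out_ch), fan_in))
        self.b = Parameter(np.zeros(out_ch), regularized=False)

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, T = x.shape
        k, pad = self.kernel, self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        # (N, C, T, k) view -> (N, T, C*k) im2col matrix
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
        cols = win.transpose(0, 2, 1, 3).reshape(N, T, C * k)
        self._cols = cols
        self._xshape = (N, C, T)
        out = cols.reshape(N * T, C * k) @ self.W.value + self.b.value
        return out.reshape(N, T, self.out_ch).transpose(0, 2, 1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        N, C, T = self._xshape
        k, pad = self.kernel, self.kernel // 2
        g = grad.transpose(0, 2, 1).reshape(N * T, self.out_ch)
        self.W.grad += self._cols.reshape(N * T, C * k).T @ g
        self.b.grad += g.sum(axis=0)
        dcols = (g @ self.W.value.T).reshape(N, T, C, k)
        dxp = np.zeros((N, C, T + 2 * pad))
        for j in range(k):  # scatter-add col2im; k is small
            dxp[:, :, j : j + T] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dxp[:, :, pad : pad + T]


class MaxPool1d(Layer):
    """Max pooling with width = stride = 2; an odd trailing sample is dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, T = x.shape
        To = T // 2
        xr = x[:, :, : 2 * To].reshape(N, C, To, 2)
        self._arg = xr.argmax(axis=3)
        self._xshape = (N, C, T)
        return xr.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        N, C, T = self._xshape
        To = T // 2
        dx = np.zeros((N, C, T))
        n, c, t = np.indices((N, C, To))
        dx[n, c, 2 * t + self._arg] = grad
        return dx


class GlobalMaxPool(Layer):
    """Max over the time axis: (N, C, T) -> (N, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._arg = x.argmax(axis=2)
        self._xshape = x.shape
        return x.max(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        N, C, _ = self._xshape
        dx = np.zeros(self._xshape)
        n, c = np.indices((N, C))
        dx[n, c, self._arg] = grad
        return dx


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._neg = x < 0
        out = np.where(self._neg, self.alpha * np.expm1(np.minimum(x, 0.0)), x)
        self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        d = np.where(self._neg, self._out + self.alpha, 1.0)
        return grad * d


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def parameters(self) -> list[Parameter]:
        return [p for lay in self.layers for p in lay.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            grad = lay.backward(grad)
        return grad


class Adam:
    """Adam optimizer over a list of :class:`Parameter` objects."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def l2_penalty(params: list[Parameter], weight: float) -> float:
    """Accumulate L2 gradients on regularized parameters; return the penalty."""
    if weight == 0.0:
        return 0.0
    total = 0.0
    for p in params:
        if p.regularized:
            total += float(np.sum(p.value**2))
            p.grad += 2.0 * weight * p.value
    return weight * total
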