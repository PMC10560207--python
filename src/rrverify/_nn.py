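"""Minimal neural-network primitives with explicit backpropagation.

Layers operate on numpy arrays: convolutional stages on (batch, channels,
length) tensors, linear stages on (batch, features) matrices.  Each layer
caches what its backward pass needs; ``backward`` consumes the gradient of
the loss with respect to its output and returns the gradient with respect
to its input, accumulating parameter gradients in ``grads``.

This module exists because the verification model is trained end to end
from the contrastive cosine loss and needs exact analytic gradients; the
layer set is deliberately restricted to what the encoder architecture uses.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


class Layer:
    """Base class: parameter-free layers inherit the empty params/grads."""

    params: List[np.ndarray]
    grads: List[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """1-D convolution with 'same' padding and stride 1.

    Weight shape (out_channels, in_channels, kernel); output length equals
    input length, so spatial size is governed by pooling alone.
    """

    def __init__(
        self, in_channels: int, out_channels: int, kernel_size: int, rng: np.random.Generator
    ) -> None:
        super().__init__()
        self.k = int(kernel_size)
        if self.k < 1:
            raise ValueError("kernel_size must be >= 1")
        fan_in = in_channels * self.k
        scale = math.sqrt(2.0 / fan_in)  # He initialization for ReLU stacks
        self.w = rng.standard_normal((out_channels, in_channels, self.k)) * scale
        bound = 1.0 / math.sqrt(fan_in)
        self.b = rng.uniform(-bound, bound, out_channels)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._pl = (self.k - 1) // 2
        self._pr = self.k // 2

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (0, 0), (self._pl, self._pr)))
        cols = sliding_window_view(xp, self.k, axis=2)  # (B, Cin, L, K)
        self._cols = cols if train else None
        self._in_len = x.shape[2]
        return np.einsum("bclk,ock->bol", cols, self.w, optimize=True) + self.b[None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols = self._cols
        self.grads[0] += np.einsum("bclk,bol->ock", cols, dout, optimize=True)
        self.grads[1] += dout.sum(axis=(0, 2))
        dcols = np.einsum("ock,bol->bclk", self.w, dout, optimize=True)
        B, C = dcols.shape[0], dcols.shape[1]
        L = self._in_len
        dxp = np.zeros((B, C, L + self._pl + self._pr))
        for k in range(self.k):
            dxp[:, :, k : k + L] += dcols[:, :, :, k]
        return dxp[:, :, self._pl : self._pl + L]


class BatchNorm(Layer):
    """Batch normalization over the batch (and, for conv inputs, length) axes.

    Accepts (B, C, L) or (B, F) inputs; learns per-channel scale/shift and
    tracks running statistics for evaluation mode.
    """

    def __init__(self, n_features: int) -> None:
        super().__init__()
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    @staticmethod
    def _axes(x: np.ndarray) -> tuple:
        return (0, 2) if x.ndim == 3 else (0,)

    def _expand(self, v: np.ndarray, ndim: int) -> np.ndarray:
        return v[None, :, None] if ndim == 3 else v[None, :]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = self._axes(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - _BN_MOMENTUM) * self.running_mean + _BN_MOMENTUM * mean
            self.running_var = (1 - _BN_MOMENTUM) * self.running_var + _BN_MOMENTUM * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - self._expand(mean, x.ndim)) * self._expand(inv, x.ndim)
        if train:
            self._xhat, self._inv, self._m = xhat, inv, x.size // x.shape[1]
        return self._expand(self.gamma, x.ndim) * xhat + self._expand(self.beta, x.ndim)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes = self._axes(dout)
        xhat, inv, m = self._xhat, self._inv, self._m
        self.grads[0] += (dout * xhat).sum(axis=axes)
        self.grads[1] += dout.sum(axis=axes)
        g = self._expand(self.gamma, dout.ndim)
        dxhat = dout * g
        term1 = dxhat - self._expand(dxhat.sum(axis=axes) / m, dout.ndim)
        term2 = xhat * self._expand((dxhat * xhat).sum(axis=axes) / m, dout.ndim)
        return self._expand(inv, dout.ndim) * (term1 - term2)


class MaxPool1d(Layer):
    """Non-overlapping max pooling with window ``size``; truncates remainders."""

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = int(size)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, L = x.shape
        Lo = L // self.size
        blocks = x[:, :, : Lo * self.size].reshape(B, C, Lo, self.size)
        arg = blocks.argmax(axis=3)
        if train:
            self._arg, self._shape = arg, x.shape
        return np.take_along_axis(blocks, arg[..., None], axis=3)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, L = self._shape
        Lo = dout.shape[2]
        dblocks = np.zeros((B, C, Lo, self.size))
        np.put_along_axis(dblocks, self._arg[..., None], dout[..., None], axis=3)
        dx = np.zeros((B, C, L))
        dx[:, :, : Lo * self.size] = dblocks.reshape(B, C, Lo * self.size)
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = math.sqrt(2.0 / in_features)
        self.w = rng.standard_normal((in_features, out_features)) * scale
        # uniform bias init keeps a dead ReLU trunk from collapsing the
        # embedding onto the exact zero vector
        bound = 1.0 / math.sqrt(in_features)
        self.b = rng.uniform(-bound, bound, out_features)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0] += self._x.T @ dout
        self.grads[1] += dout.sum(axis=0)
        return dout @ self.w.T


class Sequential:
    """Ordered layer stack with a shared forward/backward interface."""

    def __init__(self, layers: Sequence[Layer]) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self) -> List[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> List[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def zero_grad(self) -> None:
        for g in self.gradients():
            g[...] = 0.0


class SGD:
    """Stochastic gradient descent with classical momentum and weight decay."""

    def __init__(
        self,
        params: List[np.ndarray],
        grads: List[np.ndarray],
        lr: float,
        momentum: float = 0.0,
        weight_decay: float = 0.0,
    ) -> None:
        self.params = params
        self.grads = grads
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p) for p in params]

    def step(self) -> None:
        for p, g, v in zip(self.params, self.grads, self.velocity):
            update = g + self.weight_decay * p
            v *= self.momentum
            v -= self.lr * update
            p += v
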