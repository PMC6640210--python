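"""Minimal convolutional-network engine (numpy, NHWC, manual backprop).

This module provides exactly the layer zoo the segmentation networks need:
same-padding 2-D convolution, batch normalization, ReLU, 2x2 max pooling,
3x3 stride-1 max pooling, nearest-neighbor 2x upsampling, channel
concatenation, and an Adam optimizer. Convolutions are computed as im2col +
BLAS matmul; every layer caches what its backward pass needs during a
training forward pass. Activations are float32; loss reductions happen in
float64 on the caller's side.

Analytic gradients of all layers are verified against central-difference
numerical gradients in the test suite.

Conventions
-----------
* tensors are (batch, height, width, channels), float32;
* convolution weights are (k, k, c_in, c_out), He-initialized
  (std = sqrt(2 / (k*k*c_in))), biases zero;
* batch norm follows conv and precedes ReLU, with running statistics for
  inference (momentum 0.9, eps 1e-5).
"""
from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "Param",
    "Layer",
    "Conv2D",
    "BatchNorm",
    "ReLU",
    "ConvBNReLU",
    "MaxPool2x2",
    "MaxPool3x3Stride1",
    "UpsampleNearest2x",
    "Sequential",
    "Adam",
    "softmax",
    "sigmoid",
    "softmax_backward",
    "sigmoid_backward",
]

_DTYPE = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=_DTYPE)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self):
        self.grad[...] = 0.0


class Layer:
    """Forward/backward interface; backward accumulates parameter grads."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(p.size for p in self.params())


class Conv2D(Layer):
    """k x k convolution, stride 1, same padding, He-initialized."""

    def __init__(self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator):
        if c_out < 1:
            raise ValueError("c_out must be >= 1")
        fan_in = ksize * ksize * c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(ksize, ksize, c_in, c_out))
        self.w = Param(w)
        self.b = Param(np.zeros(c_out))
        self.k = ksize
        self.c_in = c_in
        self.c_out = c_out
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, H, W, C = x.shape
        k = self.k
        if k == 1:
            return x.reshape(B * H * W, C)
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # filled by k*k contiguous slice copies; a strided-view reshape here
        # would trigger a slow element-wise gather
        cols = np.empty((B, H, W, k, k, C), dtype=_DTYPE)
        for i in range(k):
            for j in range(k):
                cols[:, :, :, i, j, :] = xp[:, i : i + H, j : j + W, :]
        return cols.reshape(B * H * W, k * k * C)

    def forward(self, x, train):
        x = np.ascontiguousarray(x, dtype=_DTYPE)
        B, H, W, C = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {C}")
        cols = self._im2col(x)
        y = cols @ self.w.value.reshape(-1, self.c_out) + self.b.value
        if train:
            self._cache = (cols, x.shape)
        return y.reshape(B, H, W, self.c_out)

    def backward(self, dy):
        cols, xshape = self._cache
        B, H, W, C = xshape
        k = self.k
        dyf = np.ascontiguousarray(dy, dtype=_DTYPE).reshape(B * H * W, self.c_out)
        self.w.grad += (cols.T @ dyf).reshape(self.w.value.shape)
        self.b.grad += dyf.sum(axis=0)
        dcols = dyf @ self.w.value.reshape(-1, self.c_out).T
        if k == 1:
            return dcols.reshape(B, H, W, C)
        p = k // 2
        dwin = dcols.reshape(B, H, W, k, k, C)
        dxp = np.zeros((B, H + 2 * p, W + 2 * p, C), dtype=_DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + H, j : j + W, :] += dwin[:, :, :, i, j, :]
        return dxp[:, p : p + H, p : p + W, :]


class BatchNorm(Layer):
    """Per-channel batch normalization over (batch, height, width)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=_DTYPE)
        self.running_var = np.ones(channels, dtype=_DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv_std
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(_DTYPE)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(_DTYPE)
            self._cache = (xhat, inv_std.astype(_DTYPE))
        else:
            inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean) * inv_std
        return (self.gamma.value * xhat + self.beta.value).astype(_DTYPE)

    def backward(self, dy):
        xhat, inv_std = self._cache
        n = dy.shape[0] * dy.shape[1] * dy.shape[2]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.gamma.value
        s1 = dxhat.sum(axis=(0, 1, 2))
        s2 = (dxhat * xhat).sum(axis=(0, 1, 2))
        return (inv_std / n) * (n * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0).astype(_DTYPE)


class ConvBNReLU(Layer):
    """The conv -> batch norm -> ReLU unit used in every block."""

    def __init__(self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator):
        self.conv = Conv2D(c_in, c_out, ksize, rng)
        self.bn = BatchNorm(c_out)
        self.relu = ReLU()

    def params(self):
        return self.conv.params() + self.bn.params()

    def forward(self, x, train):
        return self.relu.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, dy):
        return self.conv.backward(self.bn.backward(self.relu.backward(dy)))


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2 (spatial dims must be even)."""

    def forward(self, x, train):
        B, H, W, C = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {H}x{W}")
        xr = x.reshape(B, H // 2, 2, W // 2, 2, C).transpose(0, 1, 3, 2, 4, 5)
        xr = xr.reshape(B, H // 2, W // 2, 4, C)
        idx = xr.argmax(axis=3)
        y = np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if train:
            self._cache = (idx, x.shape)
        return np.ascontiguousarray(y)

    def backward(self, dy):
        idx, (B, H, W, C) = self._cache
        dxr = np.zeros((B, H // 2, W // 2, 4, C), dtype=_DTYPE)
        np.put_along_axis(dxr, idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        dx = dxr.reshape(B, H // 2, W // 2, 2, 2, C).transpose(0, 1, 3, 2, 4, 5)
        return np.ascontiguousarray(dx).reshape(B, H, W, C)


class MaxPool3x3Stride1(Layer):
    """3x3 max pooling, stride 1, same padding (the Inception pooling branch)."""

    def forward(self, x, train):
        B, H, W, C = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)), constant_values=-np.inf)
        y = xp[:, 0:H, 0:W, :].copy()
        for i in range(3):
            for j in range(3):
                if i == 0 and j == 0:
                    continue
                np.maximum(y, xp[:, i : i + H, j : j + W, :], out=y)
        if train:
            self._cache = (xp, y, x.shape)
        return y

    def backward(self, dy):
        # route each pixel's gradient to the first window position attaining
        # the max (ties broken in scan order)
        xp, y, (B, H, W, C) = self._cache
        dxp = np.zeros((B, H + 2, W + 2, C), dtype=_DTYPE)
        claimed = np.zeros((B, H, W, C), dtype=bool)
        for i in range(3):
            for j in range(3):
                m = (xp[:, i : i + H, j : j + W, :] == y) & ~claimed
                dxp[:, i : i + H, j : j + W, :] += np.where(m, dy, 0.0)
                claimed |= m
        return dxp[:, 1 : 1 + H, 1 : 1 + W, :]


class UpsampleNearest2x(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy):
        B, H, W, C = self._shape
        return dy.reshape(B, H, 2, W, 2, C).sum(axis=(2, 4)).astype(_DTYPE)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


# ---------------------------------------------------------------------------
# Output activations (pixel-wise, on the trailing channel axis)

def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    return expit(z)


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    """Jacobian-vector product dL/dz given P = softmax(z) and dL/dP."""
    inner = (dprobs * probs).sum(axis=-1, keepdims=True)
    return probs * (dprobs - inner)


def sigmoid_backward(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    return dprobs * probs * (1.0 - probs)


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8) with external lr."""

    def __init__(self, params: list[Param], beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / bc1
            vhat = v / bc2
            p.value -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(_DTYPE)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
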