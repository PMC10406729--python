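"""Minimal NumPy convolutional-network core with analytic gradients.

Implements exactly the pieces the HSQC model needs — 3x3 strided
convolution (im2col), batch normalization, ReLU, global max pooling,
inverted dropout, dense layers and the Adam optimizer — in float32 NCHW
layout.  Every layer exposes ``forward(x, training)`` and ``backward(grad)``
and accumulates parameter gradients for the optimizer.  Correctness of the
backward passes is pinned by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "GlobalMaxPool",
    "Dropout",
    "Dense",
    "Adam",
    "im2col",
    "col2im",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """Unfold (N,C,H,W) into (N, C*k*k, OH*OW) patches."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    oh = (h - k) // stride + 1
    ow = (w - k) // stride + 1
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(n, c * k * k, oh * ow)


def col2im(
    gcols: np.ndarray, x_shape: tuple[int, ...], k: int, stride: int, pad: int
) -> np.ndarray:
    """Adjoint of :func:`im2col`: fold patch gradients back onto the input."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    g = gcols.reshape(n, c, k, k, oh, ow)
    gx = np.zeros((n, c, hp, wp), dtype=gcols.dtype)
    for i in range(k):
        for j in range(k):
            gx[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += g[:, :, i, j]
    if pad:
        gx = gx[:, :, pad : pad + h, pad : pad + w]
    return gx


class Conv2d:
    """k x k convolution with 'same' padding and optional stride, He init."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        stride: int = 2,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Param(rng.normal(0.0, std, size=(out_channels, fan_in)).astype(np.float32))
        self.bias = Param(np.zeros(out_channels, dtype=np.float32))
        self.kernel = kernel
        self.stride = stride
        self.pad = kernel // 2
        self.in_channels = in_channels
        self.out_channels = out_channels
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        cols = im2col(x, self.kernel, self.stride, self.pad)
        n = x.shape[0]
        oh = (x.shape[2] + 2 * self.pad - self.kernel) // self.stride + 1
        ow = (x.shape[3] + 2 * self.pad - self.kernel) // self.stride + 1
        y = np.matmul(self.weight.value, cols) + self.bias.value[None, :, None]
        self._cache = (cols, x.shape)
        return y.reshape(n, self.out_channels, oh, ow)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        n = gy.shape[0]
        g = gy.reshape(n, self.out_channels, -1)
        self.weight.grad += np.einsum("nol,nkl->ok", g, cols, optimize=True)
        self.bias.grad += g.sum(axis=(0, 2))
        gcols = np.matmul(self.weight.value.T, g)
        return col2im(gcols, x_shape, self.kernel, self.stride, self.pad)


class BatchNorm2d:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels, dtype=np.float32))
        self.beta = Param(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, training, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv_std, training, x_shape = self._cache
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        gxhat = gy * self.gamma.value[None, :, None, None]
        if not training:
            return gxhat * inv_std[None, :, None, None]
        m = x_shape[0] * x_shape[2] * x_shape[3]
        sum_g = gxhat.sum(axis=(0, 2, 3))
        sum_gx = (gxhat * xhat).sum(axis=(0, 2, 3))
        gx = (
            gxhat
            - (sum_g / m)[None, :, None, None]
            - xhat * (sum_gx / m)[None, :, None, None]
        ) * inv_std[None, :, None, None]
        return gx


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class GlobalMaxPool:
    """(N,C,H,W) -> (N,C); gradient routes to the (first) argmax cell."""

    def __init__(self):
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        flat = x.reshape(n, c, h * w)
        idx = flat.argmax(axis=2)
        self._cache = (idx, x.shape)
        return np.take_along_axis(flat, idx[:, :, None], axis=2)[:, :, 0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        gx = np.zeros((n, c, h * w), dtype=gy.dtype)
        np.put_along_axis(gx, idx[:, :, None], gy[:, :, None], axis=2)
        return gx.reshape(n, c, h, w)


class Dropout:
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()
        self._mask: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy if self._mask is None else gy * self._mask


class Dense:
    """Affine layer (N,in) -> (N,out), He init."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / in_features)
        self.weight = Param(rng.normal(0.0, std, size=(in_features, out_features)).astype(np.float32))
        self.bias = Param(np.zeros(out_features, dtype=np.float32))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ gy
        self.bias.grad += gy.sum(axis=0)
        return gy @ self.weight.value.T


class Adam:
    """Adam with optional inverse-time learning-rate decay.

    ``decay`` follows the convention of classic Keras optimizers:
    the effective rate at update t is ``lr / (1 + decay * t)``.
    """

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-5,
        decay: float = 1e-6,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ):
        self.params = params
        self.lr = lr
        self.decay = decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr / (1.0 + self.decay * (self.t - 1))
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.beta1) * (p.grad - m)
            v += (1.0 - self.beta2) * (p.grad**2 - v)
            p.value -= lr_t * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
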