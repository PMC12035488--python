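"""Minimal convolutional-network layers with explicit backprop.

Every layer follows the same contract: ``forward(x, train)`` caches what the
backward pass needs, ``backward(grad_out)`` returns the gradient with respect
to the input and accumulates parameter gradients in-place.

Internally arrays are laid out channel-first as (C, B, H, W): with the
channel axis outermost, a same-padded convolution reduces to one plain GEMM
per kernel offset on contiguous flat views — the zero padding guarantees the
row wrap-around terms of the flat shift vanish — which is what keeps this
pure-NumPy engine fast on a single core.  The engine is deliberately small
(exactly the operations the super-resolution model needs) and is validated
against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf, expit

_SQRT2 = np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


class Parameter:
    """A trainable array plus its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    """Base class; subclasses override forward/backward/parameters."""

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


class Conv2d(Layer):
    """Same-padded 2-D convolution (stride 1) on (C, B, H, W) arrays."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32, init_scale: float = 1.0):
        if kernel not in (1, 3):
            raise ValueError("kernel size must be 1 or 3")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(
            init_scale * _he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in, dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype))
        self._cache = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        if x.shape[0] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {x.shape[0]}")
        c, b, h, w = x.shape
        o = self.out_ch
        if self.kernel == 1:
            xf = np.ascontiguousarray(x).reshape(c, b * h * w)
            y = self.weight.value.reshape(o, c) @ xf
            y += self.bias.value[:, None]
            self._cache = (xf, x.shape)
            return y.reshape(o, b, h, w)
        hp, wp = h + 2, w + 2
        xp = np.zeros((c, b, hp, wp), dtype=x.dtype)
        xp[:, :, 1:1 + h, 1:1 + w] = x
        ln = b * hp * wp
        m = wp + 1  # flat margin covering the largest kernel offset
        lc = ln - 2 * m
        xf = xp.reshape(c, ln)
        wv = self.weight.value
        if o > c:
            # stack the 9 shifted planes along K: one well-shaped GEMM
            xstack = np.empty((c * 9, lc), dtype=x.dtype)
            idx = 0
            for di in range(3):
                for dj in range(3):
                    off = (di - 1) * wp + (dj - 1)
                    xstack[idx::9] = xf[:, m + off: ln - m + off]
                    idx += 1
            acc = wv.reshape(o, c * 9) @ xstack
            self._cache = (xf, xstack, x.shape, (hp, wp, ln, m))
        else:
            acc = None
            for di in range(3):
                for dj in range(3):
                    off = (di - 1) * wp + (dj - 1)
                    prod = wv[:, :, di, dj] @ xf[:, m + off: ln - m + off]
                    acc = prod if acc is None else acc + prod
            self._cache = (xf, None, x.shape, (hp, wp, ln, m))
        acc += self.bias.value[:, None]
        yf = np.zeros((o, ln), dtype=x.dtype)
        yf[:, m: ln - m] = acc
        y = np.empty((o, b, h, w), dtype=x.dtype)
        y[...] = yf.reshape(o, b, hp, wp)[:, :, 1:1 + h, 1:1 + w]
        return y

    def backward(self, grad):
        o = self.out_ch
        if self.kernel == 1:
            xf, shape = self._cache
            c, b, h, w = shape
            gf = np.ascontiguousarray(grad).reshape(o, b * h * w)
            self.weight.grad += (gf @ xf.T).reshape(self.weight.value.shape)
            self.bias.grad += gf.sum(axis=1)
            gx = self.weight.value.reshape(o, c).T @ gf
            return gx.reshape(c, b, h, w)
        xf, xstack, shape, (hp, wp, ln, m) = self._cache
        c, b, h, w = shape
        gp = np.zeros((o, b, hp, wp), dtype=grad.dtype)
        gp[:, :, 1:1 + h, 1:1 + w] = grad
        gf = gp.reshape(o, ln)
        gcore = gf[:, m: ln - m]
        self.bias.grad += gcore.sum(axis=1)
        wv = self.weight.value
        gxf = np.zeros((c, ln), dtype=grad.dtype)
        if xstack is not None:
            self.weight.grad += (gcore @ xstack.T).reshape(wv.shape)
            gxstack = wv.reshape(o, c * 9).T @ gcore
            idx = 0
            for di in range(3):
                for dj in range(3):
                    off = (di - 1) * wp + (dj - 1)
                    gxf[:, m + off: ln - m + off] += gxstack[idx::9]
                    idx += 1
        else:
            for di in range(3):
                for dj in range(3):
                    off = (di - 1) * wp + (dj - 1)
                    self.weight.grad[:, :, di, dj] += gcore @ xf[:, m + off: ln - m + off].T
                    gxf[:, m + off: ln - m + off] += wv[:, :, di, dj].T @ gcore
        gx = np.empty((c, b, h, w), dtype=grad.dtype)
        gx[...] = gxf.reshape(c, b, hp, wp)[:, :, 1:1 + h, 1:1 + w]
        return gx


class DepthwiseConv2d(Layer):
    """Per-channel 3x3 convolution (same padding) on (C, B, H, W) arrays."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator, dtype=np.float32):
        if kernel != 3:
            raise ValueError("depthwise kernel must be 3")
        self.channels, self.kernel = channels, kernel
        self.weight = Parameter(_he_init(rng, (channels, kernel, kernel), kernel * kernel, dtype))
        self.bias = Parameter(np.zeros(channels, dtype=dtype))
        self._cache = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        if x.shape[0] != self.channels:
            raise ValueError("channel mismatch in depthwise conv")
        c, b, h, w = x.shape
        hp, wp = h + 2, w + 2
        xp = np.zeros((c, b, hp, wp), dtype=x.dtype)
        xp[:, :, 1:1 + h, 1:1 + w] = x
        ln = b * hp * wp
        m = wp + 1
        xf = xp.reshape(c, ln)
        wv = self.weight.value
        acc = np.zeros((c, ln - 2 * m), dtype=x.dtype)
        for di in range(3):
            for dj in range(3):
                off = (di - 1) * wp + (dj - 1)
                acc += wv[:, di, dj, None] * xf[:, m + off: ln - m + off]
        acc += self.bias.value[:, None]
        yf = np.zeros((c, ln), dtype=x.dtype)
        yf[:, m: ln - m] = acc
        y = np.empty((c, b, h, w), dtype=x.dtype)
        y[...] = yf.reshape(c, b, hp, wp)[:, :, 1:1 + h, 1:1 + w]
        self._cache = (xf, x.shape, (hp, wp, ln, m))
        return y

    def backward(self, grad):
        xf, shape, (hp, wp, ln, m) = self._cache
        c, b, h, w = shape
        gp = np.zeros((c, b, hp, wp), dtype=grad.dtype)
        gp[:, :, 1:1 + h, 1:1 + w] = grad
        gf = gp.reshape(c, ln)
        gcore = gf[:, m: ln - m]
        self.bias.grad += gcore.sum(axis=1)
        wv = self.weight.value
        gxf = np.zeros((c, ln), dtype=grad.dtype)
        for di in range(3):
            for dj in range(3):
                off = (di - 1) * wp + (dj - 1)
                self.weight.grad[:, di, dj] += (gcore * xf[:, m + off: ln - m + off]).sum(axis=1)
                gxf[:, m + off: ln - m + off] += wv[:, di, dj, None] * gcore
        gx = np.empty((c, b, h, w), dtype=grad.dtype)
        gx[...] = gxf.reshape(c, b, hp, wp)[:, :, 1:1 + h, 1:1 + w]
        return gx


class BatchNorm2d(Layer):
    """Batch normalization over (B, H, W) per channel, with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32, beta_init: float = 0.0):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.full(channels, beta_init, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(1, 2, 3))
            var = x.var(axis=(1, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mean.astype(x.dtype)[:, None, None, None]) * inv_std[:, None, None, None]
        self._cache = (xhat, inv_std, train, x.shape)
        return self.gamma.value[:, None, None, None] * xhat + self.beta.value[:, None, None, None]

    def backward(self, grad):
        xhat, inv_std, train, shape = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(1, 2, 3))
        self.beta.grad += grad.sum(axis=(1, 2, 3))
        g = grad * self.gamma.value[:, None, None, None]
        if not train:
            return g * inv_std[:, None, None, None]
        n = shape[1] * shape[2] * shape[3]
        sum_g = g.sum(axis=(1, 2, 3), keepdims=True)
        sum_gx = (g * xhat).sum(axis=(1, 2, 3), keepdims=True)
        return (inv_std[:, None, None, None] / n) * (n * g - sum_g - xhat * sum_gx)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = expit(x)
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class GELU(Layer):
    """Exact Gaussian-error-linear unit: x * Phi(x)."""

    def forward(self, x, train=False):
        self._x = x
        self._phi = 0.5 * (1.0 + erf(x / _SQRT2))
        return x * self._phi

    def backward(self, grad):
        x = self._x
        pdf = _INV_SQRT2PI * np.exp(-0.5 * x * x)
        return grad * (self._phi + x * pdf)


class PixelShuffle(Layer):
    """Rearrange (C*r^2, B, H, W) -> (C, B, H*r, W*r)."""

    def __init__(self, r: int):
        self.r = r

    def forward(self, x, train=False):
        c, b, h, w = x.shape
        r = self.r
        if c % (r * r) != 0:
            raise ValueError("channels not divisible by r^2")
        co = c // (r * r)
        self._shape = x.shape
        y = x.reshape(co, r, r, b, h, w).transpose(0, 3, 4, 1, 5, 2)
        return np.ascontiguousarray(y).reshape(co, b, h * r, w * r)

    def backward(self, grad):
        c, b, h, w = self._shape
        r = self.r
        co = c // (r * r)
        g = grad.reshape(co, b, h, r, w, r).transpose(0, 3, 5, 1, 2, 4)
        return np.ascontiguousarray(g).reshape(c, b, h, w)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
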