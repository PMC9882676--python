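"""Minimal NumPy neural-network engine used by the 2D-to-3D networks.

Implements exactly the layer set the encoder-decoder architectures need —
strided 2D convolution, pointwise and transposed 3D convolution, batch
normalization, ReLU and sigmoid — with hand-written backward passes and an
Adam optimizer. Convolutions are expressed as im2col / col2im matrix products
so the heavy lifting runs in BLAS; all tensors are float32 and all
initialization is driven by an explicit ``numpy`` Generator, which makes
training runs bit-reproducible on a fixed device.

Array layout is channels-first: ``(N, C, H, W)`` for 2D, ``(N, C, D, H, W)``
for 3D.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def im2col(x: np.ndarray, ksize: tuple, stride: int, pad: int):
    """Unfold sliding windows of ``x`` into ``(N, C*prod(K), P)`` columns."""
    nd = len(ksize)
    if pad:
        x = np.pad(x, [(0, 0), (0, 0)] + [(pad, pad)] * nd)
    win = sliding_window_view(x, ksize, axis=tuple(range(2, 2 + nd)))
    sl = (slice(None), slice(None)) + tuple(slice(None, None, stride) for _ in range(nd))
    win = win[sl]
    out_shape = win.shape[2 : 2 + nd]
    perm = (0, 1) + tuple(range(2 + nd, 2 + 2 * nd)) + tuple(range(2, 2 + nd))
    n, c = x.shape[0], x.shape[1]
    cols = win.transpose(perm).reshape(n, c * int(np.prod(ksize)), int(np.prod(out_shape)))
    return np.ascontiguousarray(cols), out_shape


def col2im(cols: np.ndarray, xshape: tuple, ksize: tuple, stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add columns back onto the grid."""
    n, c = xshape[0], xshape[1]
    spatial = xshape[2:]
    nd = len(ksize)
    out_sp = tuple((spatial[i] + 2 * pad - ksize[i]) // stride + 1 for i in range(nd))
    g = cols.reshape((n, c) + tuple(ksize) + out_sp)
    padded = np.zeros((n, c) + tuple(s + 2 * pad for s in spatial), dtype=cols.dtype)
    for off in itertools.product(*[range(k) for k in ksize]):
        sl = (slice(None), slice(None)) + tuple(
            slice(off[i], off[i] + stride * out_sp[i], stride) for i in range(nd)
        )
        padded[sl] += g[(slice(None), slice(None)) + off]
    if pad:
        crop = (slice(None), slice(None)) + tuple(slice(pad, pad + s) for s in spatial)
        return padded[crop]
    return padded


class Layer:
    """Base class: parameters in ``self.params``, gradients in ``self.grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = math.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv(Layer):
    """N-d convolution (2D or pointwise 3D) via im2col."""

    def __init__(self, rng, in_ch: int, out_ch: int, ksize: tuple, stride: int = 1, pad: int = 0):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.ksize, self.stride, self.pad = tuple(ksize), stride, pad
        k = int(np.prod(ksize))
        self.params["w"] = _kaiming_uniform(rng, (out_ch, in_ch * k), in_ch * k)
        self.params["b"] = np.zeros(out_ch, dtype=np.float32)

    def forward(self, x, training):
        cols, out_sp = im2col(np.asarray(x), self.ksize, self.stride, self.pad)
        self._cache = (cols, x.shape)
        y = np.matmul(self.params["w"], cols) + self.params["b"][None, :, None]
        return y.reshape((x.shape[0], self.out_ch) + out_sp)

    def backward(self, gy):
        cols, xshape = self._cache
        n = gy.shape[0]
        gy_mat = gy.reshape(n, self.out_ch, -1)
        self.grads["w"] = np.matmul(gy_mat, cols.transpose(0, 2, 1)).sum(axis=0)
        self.grads["b"] = gy_mat.sum(axis=(0, 2))
        gcols = np.matmul(self.params["w"].T, gy_mat)
        return col2im(gcols, xshape, self.ksize, self.stride, self.pad)


class ConvTranspose(Layer):
    """N-d transposed convolution (used with kernel 4, stride 2, pad 1)."""

    def __init__(self, rng, in_ch: int, out_ch: int, ksize: tuple, stride: int = 2, pad: int = 1):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.ksize, self.stride, self.pad = tuple(ksize), stride, pad
        k = int(np.prod(ksize))
        # fan_in per output element is in_ch * (k / stride^nd); use in_ch * k
        self.params["w"] = _kaiming_uniform(rng, (in_ch, out_ch * k), in_ch * k)
        self.params["b"] = np.zeros(out_ch, dtype=np.float32)

    def _out_spatial(self, in_sp):
        return tuple((s - 1) * self.stride - 2 * self.pad + k for s, k in zip(in_sp, self.ksize))

    def forward(self, x, training):
        x = np.asarray(x)
        n = x.shape[0]
        in_sp = x.shape[2:]
        x_mat = x.reshape(n, self.in_ch, -1)
        self._cache = (x_mat, in_sp)
        cols = np.matmul(self.params["w"].T, x_mat)  # (N, out_ch*K, P)
        out_sp = self._out_spatial(in_sp)
        y = col2im(cols, (n, self.out_ch) + out_sp, self.ksize, self.stride, self.pad)
        return y + self.params["b"].reshape((1, self.out_ch) + (1,) * len(out_sp))

    def backward(self, gy):
        x_mat, in_sp = self._cache
        n = gy.shape[0]
        cols_g, _ = im2col(np.asarray(gy), self.ksize, self.stride, self.pad)
        gx = np.matmul(self.params["w"], cols_g).reshape((n, self.in_ch) + tuple(in_sp))
        self.grads["w"] = np.matmul(x_mat, cols_g.transpose(0, 2, 1)).sum(axis=0)
        self.grads["b"] = gy.sum(axis=(0,) + tuple(range(2, gy.ndim)))
        return gx


class BatchNorm(Layer):
    """Batch normalization over all axes except channel (axis 1)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.channels, self.momentum, self.eps = channels, momentum, eps
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def _bshape(self, ndim):
        return (1, self.channels) + (1,) * (ndim - 2)

    def forward(self, x, training):
        axes = (0,) + tuple(range(2, x.ndim))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        shape = self._bshape(x.ndim)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
        self._cache = (xhat, inv, axes, training)
        return self.params["gamma"].reshape(shape) * xhat + self.params["beta"].reshape(shape)

    def backward(self, gy):
        xhat, inv, axes, training = self._cache
        shape = self._bshape(gy.ndim)
        self.grads["gamma"] = (gy * xhat).sum(axis=axes)
        self.grads["beta"] = gy.sum(axis=axes)
        g = gy * self.params["gamma"].reshape(shape)
        if not training:
            return g * inv.reshape(shape)
        m = gy.size / gy.shape[1]
        return (
            inv.reshape(shape)
            / m
            * (m * g - g.sum(axis=axes).reshape(shape) - xhat * (g * xhat).sum(axis=axes).reshape(shape))
        )


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy):
        return np.where(self._mask, gy, 0.0)


class Sigmoid(Layer):
    def forward(self, x, training):
        from scipy.special import expit  # numerically stable sigmoid

        self._y = expit(x)
        return self._y

    def backward(self, gy):
        return gy * self._y * (1.0 - self._y)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


def iter_layers(module) -> list[Layer]:
    """Flatten a (possibly nested) module into its parameterized leaf layers."""
    if isinstance(module, Sequential):
        out = []
        for sub in module.layers:
            out.extend(iter_layers(sub))
        return out
    return [module]


class Adam:
    """Adam optimizer over a list of layers (updates parameters in place)."""

    def __init__(self, layers: list[Layer], lr: float = 2e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] += (1.0 - self.b1) * (g - m[k])
                v[k] += (1.0 - self.b2) * (g * g - v[k])
                p -= self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)
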