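"""Minimal CPU neural-network engine (NCHW, explicit forward/backward).

Provides exactly the layers HARnet needs: im2col convolutions, batch norm,
ReLU/sigmoid, 3x3 max pooling, bilinear resize (as a sparse linear map),
global average pooling, linear layers, softmax cross-entropy and Adam.
Each layer caches what its backward pass needs; composite blocks (residual
units, attention modules) orchestrate branch backward passes by hand.

float32 by default; ``dtype`` is configurable so numerical gradient checks
can run in float64.
"""

from __future__ import annotations

import contextlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import sparse

_NO_CACHE = False


@contextlib.contextmanager
def inference_mode():
    """Skip storing backward caches (halves peak memory of big forwards)."""
    global _NO_CACHE
    prev = _NO_CACHE
    _NO_CACHE = True
    try:
        yield
    finally:
        _NO_CACHE = prev


class Param:
    __slots__ = ("data", "grad")

    def __init__(self, data):
        self.data = data
        self.grad = np.zeros_like(data)


class Module:
    """Base class; submodules/params are discovered from attributes."""

    def params(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
                    elif isinstance(item, Param):
                        out.append(item)
        return out

    def forward(self, x, train=False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x, train=False):
        return self.forward(x, train=train)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


def _im2col(x, kh, kw, stride, pad):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    oh, ow = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * kh * kw)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(dcols, x_shape, kh, kw, stride, pad, oh, ow):
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += d[
                :, :, :, :, i, j
            ]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2d(Module):
    def __init__(self, cin, cout, k, stride=1, pad=None, bias=True, rng=None,
                 zero_init=False, dtype=np.float32):
        self.k, self.stride = k, stride
        self.pad = (k // 2) if pad is None else pad
        rng = rng or np.random.default_rng(0)
        if zero_init:
            w = np.zeros((cout, cin, k, k), dtype=dtype)
        else:
            std = np.sqrt(2.0 / (cin * k * k))  # He init
            w = (rng.standard_normal((cout, cin, k, k)) * std).astype(dtype)
        self.w = Param(w)
        self.b = Param(np.zeros(cout, dtype=dtype)) if bias else None
        self._cache = None

    def forward(self, x, train=False):
        cout = self.w.data.shape[0]
        cols, oh, ow = _im2col(x, self.k, self.k, self.stride, self.pad)
        wmat = self.w.data.reshape(cout, -1)
        out = cols @ wmat.T
        if self.b is not None:
            out += self.b.data
        n = x.shape[0]
        self._cache = None if _NO_CACHE else (cols, x.shape, oh, ow)
        return out.reshape(n, oh, ow, cout).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, x_shape, oh, ow = self._cache
        cout = self.w.data.shape[0]
        dmat = dout.transpose(0, 2, 3, 1).reshape(-1, cout)
        self.w.grad += (dmat.T @ cols).reshape(self.w.data.shape)
        if self.b is not None:
            self.b.grad += dmat.sum(axis=0)
        dcols = dmat @ self.w.data.reshape(cout, -1)
        return _col2im(dcols, x_shape, self.k, self.k, self.stride, self.pad, oh, ow)


class Linear(Module):
    def __init__(self, cin, cout, rng=None, zero_init=False, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        if zero_init:
            w = np.zeros((cin, cout), dtype=dtype)
        else:
            w = (rng.standard_normal((cin, cout)) * np.sqrt(2.0 / cin)).astype(dtype)
        self.w = Param(w)
        self.b = Param(np.zeros(cout, dtype=dtype))
        self._x = None

    def forward(self, x, train=False):
        self._x = None if _NO_CACHE else x
        return x @ self.w.data + self.b.data

    def backward(self, dout):
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.data.T


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5, dtype=np.float32):
        self.gamma = Param(np.ones(c, dtype=dtype))
        self.beta = Param(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = None if _NO_CACHE else (xhat, inv, train, x.shape)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dout):
        xhat, inv, train, shape = self._cache
        n = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.data[None, :, None, None]
        if not train:
            return dxhat * inv[None, :, None, None]
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        )
        return term * inv[None, :, None, None]


class ReLU(Module):
    def forward(self, x, train=False):
        if _NO_CACHE:
            return np.maximum(x, 0)
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d(Module):
    def __init__(self, k=3, stride=2, pad=1):
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        fill = np.finfo(x.dtype).min if x.dtype.kind == "f" else np.iinfo(x.dtype).min
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2),
                    constant_values=fill)
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))[
            :, :, :: self.stride, :: self.stride
        ]
        oh, ow = win.shape[2], win.shape[3]
        flat = win.reshape(n, c, oh, ow, -1)
        if not _NO_CACHE:
            self._argmax = flat.argmax(axis=-1)
            self._xshape, self._oh, self._ow = x.shape, oh, ow
        return flat.max(axis=-1)

    def backward(self, dout):
        n, c, h, w = self._xshape
        oh, ow = self._oh, self._ow
        dxp = np.zeros((n, c, h + 2 * self.pad, w + 2 * self.pad), dtype=dout.dtype)
        for kk in range(self.k * self.k):
            mask = self._argmax == kk
            if not mask.any():
                continue
            i, j = divmod(kk, self.k)
            dxp[:, :, i : i + self.stride * oh : self.stride,
                j : j + self.stride * ow : self.stride] += dout * mask
        if self.pad:
            return dxp[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return dxp


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w) + np.zeros(
            self._shape, dtype=dout.dtype
        )


def _bilinear_matrix(in_hw, out_hw, dtype):
    """Sparse (OH*OW, H*W) bilinear interpolation matrix, align_corners=False."""
    h, w = in_hw
    oh, ow = out_hw

    def axis_weights(n_in, n_out):
        scale = n_in / n_out
        src = (np.arange(n_out) + 0.5) * scale - 0.5
        i0 = np.floor(src).astype(int)
        frac = src - i0
        i0c = np.clip(i0, 0, n_in - 1)
        i1c = np.clip(i0 + 1, 0, n_in - 1)
        return i0c, i1c, 1 - frac, frac

    r0, r1, wr0, wr1 = axis_weights(h, oh)
    c0, c1, wc0, wc1 = axis_weights(w, ow)
    rows, cols, vals = [], [], []
    out_idx = np.arange(oh * ow).reshape(oh, ow)
    for ri, rw in ((r0, wr0), (r1, wr1)):
        for ci, cw in ((c0, wc0), (c1, wc1)):
            rows.append(out_idx.ravel())
            cols.append((ri[:, None] * w + ci[None, :]).ravel())
            vals.append((rw[:, None] * cw[None, :]).ravel())
    m = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(oh * ow, h * w),
    ).tocsr()
    return m.astype(dtype)


class BilinearResize(Module):
    """Bilinear up/down-sampling to a fixed output size (align_corners=False)."""

    def __init__(self, out_hw):
        self.out_hw = out_hw
        self._mats = {}

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        key = (h, w, x.dtype)
        if key not in self._mats:
            self._mats[key] = _bilinear_matrix((h, w), self.out_hw, x.dtype)
        m = self._mats[key]
        self._in_hw, self._m = (h, w), m
        out = (m @ x.reshape(n * c, h * w).T).T
        return out.reshape(n, c, *self.out_hw)

    def backward(self, dout):
        n, c = dout.shape[:2]
        oh, ow = self.out_hw
        h, w = self._in_hw
        dx = (self._m.T @ dout.reshape(n * c, oh * ow).T).T
        return dx.reshape(n, c, h, w)


def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits, labels):
    """Mean CE loss and gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (p.grad - m)
            v += (1 - self.b2) * (p.grad * p.grad - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
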