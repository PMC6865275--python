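"""Minimal neural-network layer library with explicit backward passes.

All layers operate on channel-first ``float32`` arrays ``(N, C, H, W)``
(or ``(N, D)`` for dense layers).  Each layer caches what its backward
pass needs during ``forward``; ``backward`` consumes the upstream
gradient and accumulates parameter gradients into ``Param.grad``.

Gradients accumulate across calls (needed for mini-batches assembled by
gradient accumulation); call :func:`zero_grads` before a fresh step.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "AvgPool2d",
    "MaxPool2d",
    "GlobalAvgPool",
    "Linear",
    "Dropout",
    "softmax",
    "cross_entropy",
    "zero_grads",
]


class Param:
    """A learnable tensor with its gradient accumulator.

    ``kind`` tags the parameter for initialization policy:
    ``conv_weight`` / ``fc_weight`` / ``bn_weight`` / ``bn_bias`` / ``bias``.
    """

    def __init__(self, value: np.ndarray, kind: str, name: str = ""):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.kind = kind
        self.name = name
        self.trainable = True

    def __repr__(self) -> str:  # pragma: no cover
        return f"Param({self.name or self.kind}, shape={self.value.shape})"


class Layer:
    """Base class: ``forward(x, train)`` then ``backward(dy)``."""

    def params(self) -> list[Param]:
        return []

    def children(self) -> list["Layer"]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


def zero_grads(params: list[Param]) -> None:
    for p in params:
        p.grad[...] = 0.0


# ---------------------------------------------------------------------------
# im2col helpers


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    s = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, ho, wo),
        strides=(s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride),
    )
    cols = np.ascontiguousarray(view).reshape(n, c * kh * kw, ho * wo)
    return cols, ho, wo


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    dx = np.zeros((n, c, hp, wp), dtype=np.float32)
    dcols = dcols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dcols[:, :, i, j]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


class Conv2d(Layer):
    """2-D cross-correlation with bias, via im2col matrix multiplication."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int, stride: int = 1,
                 pad: int = 0, bias: bool = True, rng: np.random.Generator | None = None,
                 name: str = "conv"):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * ksize * ksize
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, ksize, ksize))
        self.weight = Param(w, "conv_weight", f"{name}.weight")
        self.bias = Param(np.zeros(out_ch), "bias", f"{name}.bias") if bias else None
        self.stride, self.pad, self.ksize = stride, pad, ksize
        self.in_ch, self.out_ch = in_ch, out_ch
        self._cache = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=np.float32)
        cols, ho, wo = _im2col(x, self.ksize, self.ksize, self.stride, self.pad)
        wmat = self.weight.value.reshape(self.out_ch, -1)
        out = np.einsum("ok,nkp->nop", wmat, cols, optimize=True)
        if self.bias is not None:
            out += self.bias.value[None, :, None]
        self._cache = (x.shape, cols)
        return out.reshape(x.shape[0], self.out_ch, ho, wo)

    def backward(self, dy):
        x_shape, cols = self._cache
        n = dy.shape[0]
        dyf = dy.reshape(n, self.out_ch, -1)
        if self.bias is not None:
            self.bias.grad += dyf.sum(axis=(0, 2))
        dw = np.einsum("nop,nkp->ok", dyf, cols, optimize=True)
        self.weight.grad += dw.reshape(self.weight.value.shape)
        wmat = self.weight.value.reshape(self.out_ch, -1)
        dcols = np.einsum("ok,nop->nkp", wmat, dyf, optimize=True)
        return _col2im(dcols, x_shape, self.ksize, self.ksize, self.stride, self.pad)


class BatchNorm2d(Layer):
    """Batch normalization over (N, H, W) per channel with running statistics."""

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn"):
        self.weight = Param(np.ones(ch), "bn_weight", f"{name}.weight")
        self.bias = Param(np.zeros(ch), "bn_bias", f"{name}.bias")
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=np.float32)
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std, train, x.shape)
        return self.weight.value[None, :, None, None] * xhat + self.bias.value[None, :, None, None]

    def backward(self, dy):
        xhat, std, train, shape = self._cache
        self.weight.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        g = self.weight.value[None, :, None, None]
        if not train:
            return dy * g / std[None, :, None, None]
        m = shape[0] * shape[2] * shape[3]
        dxhat = dy * g
        dx = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
        return dx / std[None, :, None, None]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class AvgPool2d(Layer):
    """Non-overlapping average pooling by an integer factor (pads nothing)."""

    def __init__(self, factor: int):
        self.f = factor

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        f = self.f
        hq, wq = h // f, w // f
        self._shape = x.shape
        return x[:, :, : hq * f, : wq * f].reshape(n, c, hq, f, wq, f).mean(axis=(3, 5))

    def backward(self, dy):
        n, c, h, w = self._shape
        f = self.f
        dx = np.zeros(self._shape, dtype=np.float32)
        up = np.repeat(np.repeat(dy, f, axis=2), f, axis=3) / (f * f)
        dx[:, :, : up.shape[2], : up.shape[3]] = up
        return dx


class MaxPool2d(Layer):
    def __init__(self, ksize: int, stride: int, pad: int = 0):
        self.k, self.s, self.p = ksize, stride, pad

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.p, self.p), (self.p, self.p)),
                    constant_values=-np.inf) if self.p else x
        cols, ho, wo = _im2col(xp, self.k, self.k, self.s, 0)
        cols = cols.reshape(n, c, self.k * self.k, ho * wo)
        self._arg = cols.argmax(axis=2)
        self._dims = (x.shape, xp.shape, ho, wo)
        return cols.max(axis=2).reshape(n, c, ho, wo)

    def backward(self, dy):
        x_shape, xp_shape, ho, wo = self._dims
        n, c = x_shape[:2]
        dcols = np.zeros((n, c, self.k * self.k, ho * wo), dtype=np.float32)
        np.put_along_axis(dcols, self._arg[:, :, None, :], dy.reshape(n, c, 1, -1), axis=2)
        dxp = _col2im(dcols.reshape(n, c * self.k * self.k, ho * wo),
                      (n, c, xp_shape[2], xp_shape[3]), self.k, self.k, self.s, 0)
        if self.p:
            dxp = dxp[:, :, self.p : self.p + x_shape[2], self.p : self.p + x_shape[3]]
        return dxp


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None,
                 name: str = "fc"):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / (in_dim + out_dim)), size=(out_dim, in_dim))
        self.weight = Param(w, "fc_weight", f"{name}.weight")
        self.bias = Param(np.zeros(out_dim), "bias", f"{name}.bias")

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        self._x = np.asarray(x, dtype=np.float32)
        return self._x @ self.weight.value.T + self.bias.value

    def backward(self, dy):
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value


class Dropout(Layer):
    """Inverted dropout on a flat feature vector/batch."""

    def __init__(self, p: float = 0.5, rng: np.random.Generator | None = None):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1): {p}")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def children(self):
        return self.layers

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: np.ndarray, label: int) -> tuple[float, np.ndarray]:
    """Softmax cross-entropy for a single sample; returns (loss, dlogits)."""
    p = softmax(np.asarray(logits, dtype=np.float64).ravel())
    loss = -float(np.log(max(p[label], 1e-12)))
    dlogits = p.astype(np.float32)
    dlogits[label] -= 1.0
    return loss, dlogits
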