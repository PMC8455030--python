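"""Neural-network layers with explicit forward/backward passes.

A minimal, dependency-free CNN toolkit in NumPy: im2col convolutions,
depthwise convolution, batch normalization, ReLU6, global average pooling
and a linear head — exactly the operations the inverted-residual
classification network needs.  All tensors are NCHW float32.  Every layer's
backward pass is validated against numerical differentiation in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "DepthwiseConv2d",
    "BatchNorm2d",
    "ReLU6",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(B, C, H, W) -> (B, C, k*k, OH*OW) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (B, C, OH, OW, k, k)
    b, c, oh, ow = win.shape[:4]
    return win.transpose(0, 1, 4, 5, 2, 3).reshape(b, c, k * k, oh * ow), oh, ow


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int, oh: int, ow: int):
    """Adjoint of :func:`_im2col`: scatter-add patches back to the input."""
    b, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    dx = np.zeros((b, c, hp, wp), dtype=cols.dtype)
    cols = cols.reshape(b, c, k, k, oh, ow)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols[
                :, :, i, j
            ]
    if pad:
        dx = dx[:, :, pad : pad + h, pad : pad + w]
    return dx


class Conv2d(Layer):
    """Standard convolution (no bias; batch norm follows it everywhere).

    1x1 convolutions take a fast matmul path that skips patch extraction.
    He-style initialization.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1, seed: int = 0):
        rng = np.random.default_rng(seed)
        fan_in = c_in * k * k
        self.weight = Param(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
        )
        self.k, self.stride = k, stride
        self.pad = k // 2
        self._cache = None

    def forward(self, x, train=False):
        b = x.shape[0]
        w = self.weight.value
        c_out = w.shape[0]
        if self.k == 1:
            if self.stride > 1:
                raise NotImplementedError("strided 1x1 conv is not used by this network")
            _, c, oh, ow = x.shape
            flat = x.reshape(b, c, oh * ow)
            out = np.matmul(w[:, :, 0, 0], flat)  # (o,c) @ (b,c,l) -> (b,o,l)
            self._cache = ("pw", flat)
            return out.reshape(b, c_out, oh, ow)
        cols, oh, ow = _im2col(x, self.k, self.stride, self.pad)
        c_in = x.shape[1]
        flat = np.ascontiguousarray(cols).reshape(b, c_in * self.k * self.k, oh * ow)
        wm = w.reshape(c_out, c_in * self.k * self.k)
        out = np.matmul(wm, flat)
        self._cache = ("full", x.shape, flat, oh, ow)
        return out.reshape(b, c_out, oh, ow)

    def backward(self, dout):
        w = self.weight.value
        b, c_out, oh, ow = dout.shape
        dflat = dout.reshape(b, c_out, oh * ow)
        if self._cache[0] == "pw":
            flat = self._cache[1]
            # dW[o, i] = sum_{b,l} dout[b,o,l] x[b,i,l]
            dw = np.matmul(dflat, flat.transpose(0, 2, 1)).sum(axis=0)
            self.weight.grad += dw[:, :, None, None]
            dx = np.matmul(w[:, :, 0, 0].T, dflat)
            return dx.reshape(b, -1, oh, ow)
        _, x_shape, flat, oh, ow = self._cache
        wm = w.reshape(c_out, -1)
        dw = np.matmul(dflat, flat.transpose(0, 2, 1)).sum(axis=0)
        self.weight.grad += dw.reshape(w.shape)
        dcols = np.matmul(wm.T, dflat)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad, oh, ow)

    def params(self):
        return [self.weight]


class DepthwiseConv2d(Layer):
    """Depthwise 3x3 convolution: one k x k filter per channel."""

    def __init__(self, channels: int, k: int = 3, stride: int = 1, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.weight = Param(rng.normal(0.0, np.sqrt(2.0 / (k * k)), size=(channels, k * k)))
        self.k, self.stride = k, stride
        self.pad = k // 2
        self._cache = None

    def forward(self, x, train=False):
        # shift-and-add: a depthwise k x k conv is a weighted sum of k*k
        # shifted copies of the (padded) input
        b, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        wv = self.weight.value
        out = np.zeros((b, c, oh, ow), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                out += wv[None, :, i * k + j, None, None] * xp[
                    :, :, i : i + s * oh : s, j : j + s * ow : s
                ]
        self._cache = (x.shape, xp, oh, ow)
        return out

    def backward(self, dout):
        x_shape, xp, oh, ow = self._cache
        b, c, h, w = x_shape
        k, s, p = self.k, self.stride, self.pad
        wv = self.weight.value
        dxp = np.zeros_like(xp)
        dw = self.weight.grad
        for i in range(k):
            for j in range(k):
                sl = (slice(None), slice(None), slice(i, i + s * oh, s), slice(j, j + s * ow, s))
                dw[:, i * k + j] += (xp[sl] * dout).sum(axis=(0, 2, 3))
                dxp[sl] += wv[None, :, i * k + j, None, None] * dout
        if p:
            return dxp[:, :, p : p + h, p : p + w]
        return dxp

    def params(self):
        return [self.weight]


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (B, H, W) with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, train, x.shape)
        return (
            self.gamma.value[None, :, None, None] * xhat
            + self.beta.value[None, :, None, None]
        )

    def backward(self, dout):
        xhat, inv_std, train, shape = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not train:
            return dout * g * inv_std[None, :, None, None]
        m = shape[0] * shape[2] * shape[3]
        dxhat = dout * g
        # standard batch-norm backward: couple through batch mean and variance
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        )
        return term * inv_std[None, :, None, None]

    def params(self):
        return [self.gamma, self.beta]

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class ReLU6(Layer):
    def forward(self, x, train=False):
        self._mask = (x > 0) & (x < 6)
        return np.clip(x, 0.0, 6.0)

    def backward(self, dout):
        return dout * self._mask


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        b, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.weight = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in)))
        self.bias = Param(np.zeros(n_out))
        self._x = None

    def forward(self, x, train=False):
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dout):
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.value

    def params(self):
        return [self.weight, self.bias]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy against integer labels (0-based).

    Returns ``(loss, dlogits, probs)``; ``dlogits`` is the gradient of the
    mean loss with respect to the logits.
    """
    probs = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(probs[np.arange(n), labels] + 1e-12).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(np.float32), probs
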