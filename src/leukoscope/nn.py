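"""Minimal numpy neural-network backend.

Implements exactly the layers the dense-connectivity classifier needs —
2-D convolution (im2col), batch normalization, ReLU, average/max pooling,
global average pooling and a linear head — each with a hand-derived backward
pass, plus softmax cross-entropy and SGD with momentum and weight decay.
Gradients are verified against central finite differences in the test suite.

Activations use float32 NCHW layout. All randomness flows through an
explicit ``numpy.random.Generator`` so parameter initialization is
deterministic given a seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Param:
    """A trainable array with its gradient and a weight-decay flag."""

    __slots__ = ("name", "value", "grad", "decay")

    def __init__(self, name: str, value: np.ndarray, decay: bool = True):
        self.name = name
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.decay = decay

    def __repr__(self) -> str:  # pragma: no cover
        return f"Param({self.name}, shape={self.value.shape})"


class Layer:
    """Base class: forward caches what backward needs; params() yields Params."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    h_out = (h + 2 * pad - k) // stride + 1
    w_out = (w + 2 * pad - k) // stride + 1
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    # (n, c, h_out, w_out, k, k) -> (n*h_out*w_out, c*k*k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h_out * w_out, c * k * k)
    return np.ascontiguousarray(cols), (h_out, w_out)


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    h_out = (h + 2 * pad - k) // stride + 1
    w_out = (w + 2 * pad - k) // stride + 1
    d = dcols.reshape(n, h_out, w_out, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    dx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dx[:, :, i:i + stride * h_out:stride, j:j + stride * w_out:stride] += d[:, :, :, :, i, j]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


class Conv2d(Layer):
    """Convolution without bias (batch norm follows every conv here)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None, name: str = "conv"):
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = c_in * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        self.weight = Param(f"{name}.weight", w, decay=True)
        self._cache = None

    def params(self):
        return [self.weight]

    def forward(self, x, train):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        cols, (h_out, w_out) = _im2col(x, self.kernel, self.stride, self.pad)
        out = cols @ self.weight.value
        n = x.shape[0]
        self._cache = (cols, x.shape, h_out, w_out)
        return out.reshape(n, h_out, w_out, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad):
        cols, x_shape, h_out, w_out = self._cache
        n = x_shape[0]
        dout = grad.transpose(0, 2, 3, 1).reshape(n * h_out * w_out, self.c_out)
        self.weight.grad = (cols.T @ dout).astype(DTYPE)
        dcols = dout @ self.weight.value.T
        return _col2im(dcols, x_shape, self.kernel, self.stride, self.pad)


class BatchNorm2d(Layer):
    def __init__(self, channels: int, name: str = "bn", momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Param(f"{name}.gamma", np.ones(channels), decay=False)
        self.beta = Param(f"{name}.beta", np.zeros(channels), decay=False)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std) if train else None
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad):
        xhat, inv_std = self._cache
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.dgamma_dbeta(grad, xhat)
        dxhat = grad * self.gamma.value[None, :, None, None]
        sum_dxhat = dxhat.sum(axis=(0, 2, 3))
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3))
        dx = (dxhat - (sum_dxhat[None, :, None, None]
                       + xhat * sum_dxhat_xhat[None, :, None, None]) / m)
        return dx * inv_std[None, :, None, None]

    def dgamma_dbeta(self, grad, xhat):
        self.gamma.grad = (grad * xhat).sum(axis=(0, 2, 3)).astype(DTYPE)
        self.beta.grad = grad.sum(axis=(0, 2, 3)).astype(DTYPE)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class AvgPool2d(Layer):
    """Non-overlapping 2x2 average pooling (truncates odd trailing rows/cols)."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, train):
        s = self.size
        n, c, h, w = x.shape
        h2, w2 = h // s, w // s
        self._in_shape = x.shape
        x = x[:, :, :h2 * s, :w2 * s]
        return x.reshape(n, c, h2, s, w2, s).mean(axis=(3, 5))

    def backward(self, grad):
        s = self.size
        n, c, h, w = self._in_shape
        h2, w2 = h // s, w // s
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        dx[:, :, :h2 * s, :w2 * s] = np.repeat(
            np.repeat(grad, s, axis=2), s, axis=3) / (s * s)
        return dx


class MaxPool2d(Layer):
    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, train):
        s = self.size
        n, c, h, w = x.shape
        h2, w2 = h // s, w // s
        self._in_shape = x.shape
        xr = x[:, :, :h2 * s, :w2 * s].reshape(n, c, h2, s, w2, s)
        out = xr.max(axis=(3, 5))
        is_max = xr == out[:, :, :, None, :, None]
        # break ties deterministically: keep only the first max per window
        flat = is_max.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, s * s)
        first = flat & (np.cumsum(flat, axis=-1) == 1)
        self._argmask = first.reshape(n, c, h2, w2, s, s).transpose(0, 1, 2, 4, 3, 5)
        return out

    def backward(self, grad):
        s = self.size
        n, c, h, w = self._in_shape
        h2, w2 = h // s, w // s
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        dx[:, :, :h2 * s, :w2 * s] = (
            self._argmask * grad[:, :, :, None, :, None]
        ).reshape(n, c, h2 * s, w2 * s)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._in_shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w), self._in_shape).copy()


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 name: str = "linear", weight_scale: float = 0.01):
        self.weight = Param(f"{name}.weight",
                            rng.normal(0.0, weight_scale, size=(n_in, n_out)), decay=True)
        self.bias = Param(f"{name}.bias", np.zeros(n_out), decay=False)

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train):
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, grad):
        self.weight.grad = (self._x.T @ grad).astype(DTYPE)
        self.bias.grad = grad.sum(axis=0).astype(DTYPE)
        return grad @ self.weight.value.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean softmax cross-entropy; returns (loss, dloss/dlogits)."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = float(-np.log(np.maximum(p[np.arange(n), targets], 1e-30)).mean())
    dlogits = p
    dlogits[np.arange(n), targets] -= 1.0
    return loss, (dlogits / n).astype(DTYPE)


class SGD:
    """Plain SGD with momentum and decoupled-from-nothing L2 weight decay."""

    def __init__(self, params: list[Param], momentum: float = 0.9,
                 weight_decay: float = 1e-4):
        self.params = list(params)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.value) for p in self.params]

    def step(self, lr: float) -> None:
        for p, v in zip(self.params, self._velocity):
            g = p.grad
            if p.decay and self.weight_decay:
                g = g + self.weight_decay * p.value
            v *= self.momentum
            v -= lr * g
            p.value += v
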