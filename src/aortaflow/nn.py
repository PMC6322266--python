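"""Minimal CNN engine: layers with explicit forward/backward passes.

The segmentation network is small enough (depth 3-5, 8-32 base filters,
2D inputs) that a self-contained NumPy engine with hand-derived gradients
is fast, dependency-free and bit-reproducible.  Convolutions use the
im2col/col2im formulation so the heavy lifting is a single BLAS matmul per
layer.  All parameters and activations are float32; a layer owns its
parameters, gradients and the caches needed for the backward pass (one
batch in flight at a time).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "ReLU",
    "MaxPool2x2",
    "Upsample2x",
    "weighted_softmax_ce",
    "softmax",
    "RMSProp",
]


class Layer:
    """Base: layers expose forward/backward and optional (params, grads)."""

    def parameters(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        return []


class Conv2d(Layer):
    """k x k same-padding convolution, stride 1, He-normal initialization."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator, name: str):
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.name = name
        fan_in = in_ch * kernel * kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, kernel, kernel)).astype(
            np.float32
        )
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def parameters(self):
        return [(f"{self.name}.W", self.W, self.dW), (f"{self.name}.b", self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.kernel
        p = k // 2
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(x, (k, k), axis=(2, 3))  # (n,c,h,w,k,k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * k * k
        )
        out = cols @ self.W.reshape(self.out_ch, -1).T + self.b
        if train:
            self._cols = cols
            self._in_shape = (n, c, h, w)
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        k = self.kernel
        p = k // 2
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_ch)
        self.dW += (dmat.T @ self._cols).reshape(self.W.shape)
        self.db += dmat.sum(axis=0)
        dcols = dmat @ self.W.reshape(self.out_ch, -1)  # (n*h*w, c*k*k)
        dcols = dcols.reshape(n, h, w, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di : di + h, dj : dj + w] += dcols[:, :, :, :, di, dj]
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2; input H, W must be even."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        if train:
            mask = xr == out[:, :, :, None, :, None]
            # break ties toward the first max so the gradient is not duplicated;
            # window axes (3, 5) are flattened together via an explicit transpose
            flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
            first = np.argmax(flat, axis=-1)
            tie_free = np.zeros_like(flat)
            np.put_along_axis(tie_free, first[..., None], True, axis=-1)
            self._argmask = tie_free.reshape(n, c, h // 2, w // 2, 2, 2).transpose(
                0, 1, 2, 4, 3, 5
            )
            self._in_shape = (n, c, h, w)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        dx = self._argmask * dout[:, :, :, None, :, None]
        return dx.reshape(n, c, h, w).astype(np.float32)


class Upsample2x(Layer):
    """Nearest-neighbor 2x upsampling."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def weighted_softmax_ce(
    logits: np.ndarray,
    truth: np.ndarray,
    class_weights: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Class-weighted softmax cross-entropy, mean over pixels and frames.

    Per pixel with logit vector x and true class i:
    loss = -w[i] * ln( e^{x[i]} / sum_j e^{x[j]} ), computed through a
    stabilized log-sum-exp.  Returns (scalar loss, d loss / d logits).

    Parameters
    ----------
    logits : (N, C, H, W) float array
    truth : (N, H, W) integer class labels
    class_weights : (C,) nonnegative weights
    """
    w = np.asarray(class_weights, dtype=np.float64)
    if (w < 0).any():
        raise ValueError(f"class weights must be nonnegative, got {w}")
    n, c, h, w_ = logits.shape
    if truth.shape != (n, h, w_):
        raise ValueError(f"truth shape {truth.shape} != {(n, h, w_)}")
    z = logits.astype(np.float64)
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    logp = z - lse  # (N,C,H,W)
    t = truth.astype(np.intp)
    logp_true = np.take_along_axis(logp, t[:, None], axis=1)[:, 0]
    wt = w[t]
    npix = t.size
    loss = float(-(wt * logp_true).sum() / npix)

    p = np.exp(logp)
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, t[:, None], 1.0, axis=1)
    dlogits = (wt[:, None] * (p - onehot) / npix).astype(np.float32)
    return loss, dlogits


class RMSProp:
    """RMSProp: cache = rho*cache + (1-rho)*g^2; p -= lr * g / (sqrt(cache)+eps)."""

    def __init__(self, params, lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-8):
        self.params = list(params)  # [(name, param, grad)]
        self.lr, self.rho, self.eps = lr, rho, eps
        self.cache = {name: np.zeros_like(p) for name, p, _ in self.params}

    def zero_grad(self) -> None:
        for _, _, g in self.params:
            g[...] = 0.0

    def step(self) -> None:
        for name, p, g in self.params:
            c = self.cache[name]
            c *= self.rho
            c += (1.0 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(c) + self.eps)
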