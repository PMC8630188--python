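"""Minimal CPU neural-network engine (numpy, channels-last).

Implements exactly the pieces the tile classifiers need — valid-padding
convolution via im2col, ReLU, 2x2 max pooling, global average pooling,
dropout, a dense head, softmax cross-entropy with class weights, and Adam
with decoupled weight decay.  Everything is seeded and single-threaded
numpy, so training runs are bit-reproducible on CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "GlobalAvgPool",
    "Dropout",
    "Dense",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N,H,W,C) -> (N,Ho,Wo,kh*kw*C) patch matrix, stride 1, valid."""
    v = sliding_window_view(x, (kh, kw), axis=(1, 2))  # (N,Ho,Wo,C,kh,kw)
    n, ho, wo = v.shape[:3]
    cols = v.transpose(0, 1, 2, 4, 5, 3).reshape(n, ho, wo, kh * kw * x.shape[3])
    return np.ascontiguousarray(cols)


class Conv2D:
    """Valid-padding stride-1 convolution (cross-correlation convention)."""

    def __init__(self, c_in: int, n_filters: int, kernel: int, rng: np.random.Generator):
        fan_in = kernel * kernel * c_in
        scale = np.sqrt(2.0 / fan_in)
        self.W = rng.normal(0.0, scale, size=(kernel, kernel, c_in, n_filters)).astype(
            np.float32
        )
        self.b = np.zeros(n_filters, dtype=np.float32)
        self.kernel = kernel
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k = self.kernel
        cols = _im2col(x, k, k)
        wmat = self.W.reshape(-1, self.W.shape[-1])
        out = cols @ wmat + self.b
        self._cache = (x.shape, cols)
        return out

    def backward(self, dy: np.ndarray):
        x_shape, cols = self._cache
        k = self.kernel
        n, ho, wo, nf = dy.shape
        wmat = self.W.reshape(-1, nf)
        dcols = dy @ wmat.T
        dW = cols.reshape(-1, cols.shape[-1]).T @ dy.reshape(-1, nf)
        db = dy.sum(axis=(0, 1, 2))
        # scatter column gradients back to the input grid
        dx = np.zeros(x_shape, dtype=dy.dtype)
        dcols = dcols.reshape(n, ho, wo, k, k, x_shape[3])
        for i in range(k):
            for j in range(k):
                dx[:, i : i + ho, j : j + wo, :] += dcols[:, :, :, i, j, :]
        return dx, [dW.reshape(self.W.shape), db]


class ReLU:
    params = ()

    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask, []


class MaxPool2:
    """2x2 max pooling, stride 2; trailing odd row/col cropped."""

    params = ()

    def forward(self, x, train):
        n, h, w, c = x.shape
        ho, wo = h // 2, w // 2
        xr = x[:, : ho * 2, : wo * 2].reshape(n, ho, 2, wo, 2, c)
        xr = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, ho, wo, c, 4)
        self._argmax = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, h, w, c = self._in_shape
        ho, wo = h // 2, w // 2
        flat = np.zeros((n, ho, wo, c, 4), dtype=dy.dtype)
        np.put_along_axis(flat, self._argmax[..., None], dy[..., None], axis=-1)
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, : ho * 2, : wo * 2] = (
            flat.reshape(n, ho, wo, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, ho * 2, wo * 2, c)
        )
        return dx, []


class GlobalAvgPool:
    params = ()

    def forward(self, x, train):
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        n, h, w, c = self._in_shape
        dx = np.broadcast_to(dy[:, None, None, :] / (h * w), self._in_shape)
        return np.ascontiguousarray(dx), []


class Dropout:
    """Inverted dropout; identity at inference."""

    params = ()

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy, []
        return dy * self._mask, []


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        dW = self._x.T @ dy
        db = dy.sum(axis=0)
        return dy @ self.W.T, [dW, db]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, sample_weight: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean weighted cross-entropy and gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits)
    w = np.ones(n) if sample_weight is None else sample_weight
    eps = 1e-12
    loss = float(-(w * np.log(p[np.arange(n), labels] + eps)).sum() / w.sum())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    grad *= (w / w.sum())[:, None]
    return loss, grad.astype(np.float32)


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    @property
    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> list[np.ndarray]:
        grads: list[np.ndarray] = []
        for layer in reversed(self.layers):
            dy, g = layer.backward(dy)
            grads = g + grads
        return grads


class Adam:
    """Adam with decoupled weight decay (applied to weights, not biases)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        weight_decay: float = 0.0,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, (p, g) in enumerate(zip(self.params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and p.ndim > 1:
                p -= self.lr * self.weight_decay * p
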