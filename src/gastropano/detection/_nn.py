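"""Minimal CPU neural-network layers (forward + manual backward).

Just enough machinery for the small single-shot detector: 3x3 and 1x1
convolutions (im2col), ReLU, 2x2 max pooling, and Adam.  Everything is
float64 numpy, deterministic given the seed and single-threaded BLAS.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ReLU", "MaxPool2", "Sequential", "Adam"]


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(C,H,W) -> (H*W, C*k*k) patch matrix for stride-1 convolution."""
    C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    # gather k*k shifted views
    cols = np.empty((C, k * k, H, W))
    for i in range(k):
        for j in range(k):
            cols[:, i * k + j] = xp[:, i : i + H, j : j + W]
    return cols.reshape(C * k * k, H * W).T


class Conv2d:
    """Stride-1 same-padding convolution, kernel k in {1, 3}."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        fan_in = c_in * k * k
        self.w = rng.normal(0, np.sqrt(2.0 / fan_in), (c_out, c_in * k * k))
        self.b = np.zeros(c_out)
        self._cache = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        C, H, W = x.shape
        cols = _im2col(x, self.k, self.k // 2)  # (H*W, C*k*k)
        out = cols @ self.w.T + self.b  # (H*W, c_out)
        self._cache = (cols, (H, W))
        return out.T.reshape(self.c_out, H, W)

    def backward(self, grad: np.ndarray):
        cols, (H, W) = self._cache
        g = grad.reshape(self.c_out, H * W).T  # (H*W, c_out)
        self.gw = g.T @ cols
        self.gb = g.sum(axis=0)
        gcols = g @ self.w  # (H*W, C*k*k)
        # scatter back (col2im)
        k, pad = self.k, self.k // 2
        gx = np.zeros((self.c_in, H + 2 * pad, W + 2 * pad))
        gc = gcols.T.reshape(self.c_in, k * k, H, W)
        for i in range(k):
            for j in range(k):
                gx[:, i : i + H, j : j + W] += gc[:, i * k + j]
        if pad:
            gx = gx[:, pad:-pad, pad:-pad]
        return gx

    @property
    def grads(self):
        return [self.gw, self.gb]


class ReLU:
    params: list = []
    grads: list = []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped."""

    params: list = []
    grads: list = []

    def forward(self, x):
        C, H, W = x.shape
        H2, W2 = H // 2, W // 2
        xv = x[:, : 2 * H2, : 2 * W2].reshape(C, H2, 2, W2, 2)
        xf = xv.transpose(0, 1, 3, 2, 4).reshape(C, H2, W2, 4)
        self._arg = xf.argmax(axis=3)
        self._shape = (C, H, W)
        return xf.max(axis=3)

    def backward(self, grad):
        C, H, W = self._shape
        H2, W2 = H // 2, W // 2
        gx = np.zeros((C, H2, W2, 4))
        np.put_along_axis(gx, self._arg[..., None], grad[..., None], axis=3)
        gx = gx.reshape(C, H2, W2, 2, 2).transpose(0, 1, 3, 2, 4).reshape(C, 2 * H2, 2 * W2)
        out = np.zeros((C, H, W))
        out[:, : 2 * H2, : 2 * W2] = gx
        return out


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]


class Adam:
    def __init__(self, params: list[np.ndarray], lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)
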