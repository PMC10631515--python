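"""Minimal CPU convolutional-network primitives (numpy forward/backward).

Just enough machinery for the thickness-map correction network: 3x3
same-padding convolutions, ReLU, 2x2 average pooling, nearest-neighbor
x2 upsampling, channel concatenation, a dense layer, row-wise L2
normalization, and an Adam optimizer over a flat parameter dict. Each
layer is a pure forward function returning ``(output, cache)`` plus a
matching backward function; the network class wires them together.

Convolutions are computed as nine shifted channel-mixing products
(one per kernel tap), which keeps both passes allocation-light and
exactly symmetric between forward and backward.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


def conv3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """3x3 convolution, stride 1, zero same-padding.

    x: (N, C, H, W); w: (F, C, 3, 3); b: (F,) -> y: (N, F, H, W)
    """
    n, c, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    y = np.zeros((n, w.shape[0], h, wd))
    for i in range(3):
        for j in range(3):
            y += np.einsum(
                "fc,nchw->nfhw", w[:, :, i, j], xp[:, :, i : i + h, j : j + wd],
                optimize=True,
            )
    y += b[None, :, None, None]
    return y, (xp, w)


def conv3_backward(dy: np.ndarray, cache):
    xp, w = cache
    n, f, h, wd = dy.shape
    dw = np.zeros_like(w)
    dxp = np.zeros_like(xp)
    for i in range(3):
        for j in range(3):
            dw[:, :, i, j] = np.einsum(
                "nfhw,nchw->fc", dy, xp[:, :, i : i + h, j : j + wd], optimize=True
            )
            dxp[:, :, i : i + h, j : j + wd] += np.einsum(
                "fc,nfhw->nchw", w[:, :, i, j], dy, optimize=True
            )
    db = dy.sum(axis=(0, 2, 3))
    return dxp[:, :, 1:-1, 1:-1], dw, db


def conv1_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """1x1 convolution (pure channel mixing). w: (F, C)."""
    y = np.einsum("fc,nchw->nfhw", w, x, optimize=True) + b[None, :, None, None]
    return y, (x, w)


def conv1_backward(dy: np.ndarray, cache):
    x, w = cache
    dw = np.einsum("nfhw,nchw->fc", dy, x, optimize=True)
    dx = np.einsum("fc,nfhw->nchw", w, dy, optimize=True)
    db = dy.sum(axis=(0, 2, 3))
    return dx, dw, db


def relu_forward(x: np.ndarray):
    y = np.maximum(x, 0.0)
    return y, (x > 0)


def relu_backward(dy: np.ndarray, cache):
    return dy * cache


def avgpool2_forward(x: np.ndarray):
    n, c, h, w = x.shape
    y = x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))
    return y, x.shape


def avgpool2_backward(dy: np.ndarray, x_shape):
    n, c, h, w = x_shape
    return np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) / 4.0


def upsample2_forward(x: np.ndarray):
    y = np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)
    return y, x.shape


def upsample2_backward(dy: np.ndarray, x_shape):
    n, c, h, w = x_shape
    return dy.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))


def dense_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """x: (N, D_in); w: (D_out, D_in); b: (D_out,)."""
    return x @ w.T + b, (x, w)


def dense_backward(dy: np.ndarray, cache):
    x, w = cache
    return dy @ w, dy.T @ x, dy.sum(axis=0)


def l2norm_forward(x: np.ndarray, eps: float = 1e-12):
    norm = np.sqrt((x**2).sum(axis=1, keepdims=True)) + eps
    z = x / norm
    return z, (z, norm)


def l2norm_backward(dz: np.ndarray, cache):
    z, norm = cache
    return (dz - (dz * z).sum(axis=1, keepdims=True) * z) / norm


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Adam over a dict of named parameter arrays (updated in place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 2e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
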