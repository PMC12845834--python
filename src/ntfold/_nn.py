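"""Minimal NumPy neural-network primitives with analytic gradients.

Forward functions return (output, cache); matching backward functions take the
upstream gradient plus the cache and return gradients with respect to inputs
and parameters.  Everything operates on float64 (B, C, H, W) arrays; the model
sizes used in this package are small enough that exactness and reproducibility
beat GPU-style throughput.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv2d",
    "conv2d_backward",
    "relu",
    "relu_backward",
    "sigmoid",
    "maxpool2",
    "maxpool2_backward",
    "upsample2",
    "upsample2_backward",
    "softmax_rows",
    "softmax_rows_backward",
    "Adam",
]


def conv2d(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-padded 2-D convolution. x: (B,C,H,Wd), W: (O,C,kh,kw), b: (O,)."""
    B, C, H, Wd = x.shape
    O, C2, kh, kw = W.shape
    assert C == C2, f"channel mismatch {C} vs {C2}"
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    y = np.zeros((B, H, Wd, O))
    for di in range(kh):
        for dj in range(kw):
            # (B,H,Wd,C) . (C,O) contracted over channels
            y += np.tensordot(
                xp[:, :, di : di + H, dj : dj + Wd], W[:, :, di, dj], axes=([1], [1])
            )
    y = y.transpose(0, 3, 1, 2) + b.reshape(1, O, 1, 1)
    return y, (xp, W.shape, x.shape)


def conv2d_backward(dy: np.ndarray, W: np.ndarray, cache):
    xp, wshape, xshape = cache
    B, C, H, Wd = xshape
    O, _, kh, kw = wshape
    ph, pw = kh // 2, kw // 2
    db = dy.sum(axis=(0, 2, 3))
    dW = np.zeros(wshape)
    dxp = np.zeros_like(xp)
    for di in range(kh):
        for dj in range(kw):
            patch = xp[:, :, di : di + H, dj : dj + Wd]
            dW[:, :, di, dj] = np.tensordot(dy, patch, axes=([0, 2, 3], [0, 2, 3]))
            dxp[:, :, di : di + H, dj : dj + Wd] += np.tensordot(
                dy, W[:, :, di, dj], axes=([1], [0])
            ).transpose(0, 3, 1, 2)
    dx = dxp[:, :, ph : ph + H, pw : pw + Wd] if (ph or pw) else dxp
    return dx, dW, db


def relu(x: np.ndarray):
    y = np.maximum(x, 0.0)
    return y, (x > 0.0)


def relu_backward(dy: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dy * mask


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def maxpool2(x: np.ndarray):
    """2x2 max pooling, stride 2; H and W must be even."""
    B, C, H, Wd = x.shape
    xr = x.reshape(B, C, H // 2, 2, Wd // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = xr.reshape(B, C, H // 2, Wd // 2, 4)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return y, (idx, x.shape)


def maxpool2_backward(dy: np.ndarray, cache) -> np.ndarray:
    idx, xshape = cache
    B, C, H, Wd = xshape
    dflat = np.zeros((B, C, H // 2, Wd // 2, 4))
    np.put_along_axis(dflat, idx[..., None], dy[..., None], axis=-1)
    return (
        dflat.reshape(B, C, H // 2, Wd // 2, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(B, C, H, Wd)
    )


def upsample2(x: np.ndarray) -> np.ndarray:
    """Nearest-neighbour 2x upsampling."""
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    B, C, H, Wd = dy.shape
    return dy.reshape(B, C, H // 2, 2, Wd // 2, 2).sum(axis=(3, 5))


def softmax_rows(s: np.ndarray) -> np.ndarray:
    """Row-wise softmax over the last axis, numerically stabilised."""
    z = s - s.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_rows_backward(dy: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Jacobian-vector product of row softmax: ds = y * (dy - sum(dy*y))."""
    return y * (dy - (dy * y).sum(axis=-1, keepdims=True))


class Adam:
    """Adam optimiser over a dict of named parameter arrays (updates in place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
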