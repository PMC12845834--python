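"""Structural refinement: a small U-Net over the L x L correlation map.

The raw attention-derived map is noisy and asymmetric; stems appear in it as
faint anti-diagonal line segments.  A convolutional encoder-decoder with skip
connections cleans it up: the encoder path downsamples (2x max-pool per level)
so deeper levels integrate longer-range context, and the decoder path upsamples
and concatenates the matching encoder feature map before each conv block.

Input maps are padded on the right/bottom to the next multiple of 2^n, cropped
back after decoding, squashed through a logistic so entries are probability
like, and symmetrised as (X + X^T)/2 before return.

By default the single-channel map is stacked with two normalised coordinate
channels (i/S, j/S over the padded grid) so the network can express
position-dependent range behaviour; this is configurable off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import (
    conv2d,
    conv2d_backward,
    maxpool2,
    maxpool2_backward,
    relu,
    relu_backward,
    sigmoid,
    upsample2,
    upsample2_backward,
)

__all__ = ["RefinementParams", "refine", "refine_batch", "refine_batch_backward"]


def _he(rng: np.random.Generator, o: int, c: int, k: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / (c * k * k)), size=(o, c, k, k))


@dataclass
class RefinementParams:
    """U-Net weights: per level one conv block (two 3x3 convs + ReLU) on the
    encoder and decoder paths, plus a final 1x1 projection."""

    n: int
    base: int
    use_coords: bool
    identity: bool  # ablation: skip the network, squash + symmetrise only
    params: dict[str, np.ndarray] = field(repr=False)

    def __init__(self, n: int = 2, base: int = 16, use_coords: bool = True,
                 identity: bool = False, params: dict | None = None,
                 rng: np.random.Generator | None = None):
        if n < 1 or base < 1:
            raise ValueError("depth n and base channel count must be >= 1")
        self.n, self.base, self.use_coords, self.identity = n, base, use_coords, identity
        if params is not None:
            self.params = params
            return
        rng = rng or np.random.default_rng(0)
        c_in = 3 if use_coords else 1
        enc = [c_in] + [base * 2 ** k for k in range(n)]
        p: dict[str, np.ndarray] = {}
        for k in range(1, n + 1):  # F_k = ConvBlock_k(Down(F_{k-1}))
            p[f"enc{k}_w1"] = _he(rng, enc[k], enc[k - 1], 3)
            p[f"enc{k}_b1"] = np.zeros(enc[k])
            p[f"enc{k}_w2"] = _he(rng, enc[k], enc[k], 3)
            p[f"enc{k}_b2"] = np.zeros(enc[k])
        for k in range(1, n + 1):  # G_k = ConvBlock'_k(Up(G_{k-1}) || F_{n-k})
            skip = enc[n - k]
            prev = enc[n] if k == 1 else self._dec_out(enc, k - 1)
            out = self._dec_out(enc, k)
            p[f"dec{k}_w1"] = _he(rng, out, prev + skip, 3)
            p[f"dec{k}_b1"] = np.zeros(out)
            p[f"dec{k}_w2"] = _he(rng, out, out, 3)
            p[f"dec{k}_b2"] = np.zeros(out)
        p["out_w"] = _he(rng, 1, self._dec_out(enc, n), 1)
        p["out_b"] = np.zeros(1)
        self.params = p

    def _dec_out(self, enc: list[int], k: int) -> int:
        # decoder block k mirrors encoder level n-k; the last block outputs `base`
        return enc[self.n - k] if k < self.n else self.base

    @property
    def factor(self) -> int:
        return 2 ** self.n


def _conv_block(x, p, prefix):
    y1, c1 = conv2d(x, p[f"{prefix}_w1"], p[f"{prefix}_b1"])
    a1, m1 = relu(y1)
    y2, c2 = conv2d(a1, p[f"{prefix}_w2"], p[f"{prefix}_b2"])
    a2, m2 = relu(y2)
    return a2, (c1, m1, c2, m2)


def _conv_block_backward(da2, p, prefix, cache, grads):
    c1, m1, c2, m2 = cache
    dy2 = relu_backward(da2, m2)
    da1, dw2, db2 = conv2d_backward(dy2, p[f"{prefix}_w2"], c2)
    dy1 = relu_backward(da1, m1)
    dx, dw1, db1 = conv2d_backward(dy1, p[f"{prefix}_w1"], c1)
    grads[f"{prefix}_w1"] = dw1
    grads[f"{prefix}_b1"] = db1
    grads[f"{prefix}_w2"] = dw2
    grads[f"{prefix}_b2"] = db2
    return dx


def _stack_input(C: np.ndarray, params: RefinementParams) -> tuple[np.ndarray, int]:
    """Pad (B,L,L) maps to the pooling factor and add coordinate channels."""
    B, L, _ = C.shape
    f = params.factor
    S = -(-L // f) * f
    x = np.zeros((B, 3 if params.use_coords else 1, S, S))
    x[:, 0, :L, :L] = C
    if params.use_coords:
        coord = (np.arange(S) + 0.5) / S
        x[:, 1] = coord[:, None]
        x[:, 2] = coord[None, :]
    return x, S


def refine_batch(C: np.ndarray, params: RefinementParams):
    """Refine a batch of maps (B, L, L) -> (B, L, L) in [0,1], symmetric.

    Returns (refined, cache) where cache supports the matching backward pass.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 3 or C.shape[1] != C.shape[2]:
        raise ValueError("expected a batch of square maps (B, L, L)")
    B, L, _ = C.shape
    if L == 0:
        raise ValueError("empty map")
    if params.identity:
        sig = sigmoid(C)
        out = 0.5 * (sig + sig.transpose(0, 2, 1))
        return out, ("identity", sig)

    p = params.params
    x, S = _stack_input(C, params)
    feats = [x]  # F_0 .. F_n
    enc_caches = []
    for k in range(1, params.n + 1):
        pooled, pc = maxpool2(feats[-1])
        f, bc = _conv_block(pooled, p, f"enc{k}")
        enc_caches.append((pc, bc))
        feats.append(f)
    g = feats[-1]
    dec_caches = []
    for k in range(1, params.n + 1):
        up = upsample2(g)
        skip = feats[params.n - k]
        cat = np.concatenate([up, skip], axis=1)
        g, bc = _conv_block(cat, p, f"dec{k}")
        dec_caches.append((up.shape[1], bc))
    y, out_cache = conv2d(g, p["out_w"], p["out_b"])
    logits = y[:, 0, :L, :L]
    sig = sigmoid(logits)
    out = 0.5 * (sig + sig.transpose(0, 2, 1))
    cache = ("unet", S, L, enc_caches, dec_caches, out_cache, sig)
    return out, cache


def refine_batch_backward(dout: np.ndarray, params: RefinementParams, cache):
    """Gradients w.r.t. parameters (and the input map) given dL/d(refined)."""
    if cache[0] == "identity":
        sig = cache[1]
        dsig = 0.5 * (dout + dout.transpose(0, 2, 1))
        dC = dsig * sig * (1.0 - sig)
        return {}, dC

    _, S, L, enc_caches, dec_caches, out_cache, sig = cache
    p = params.params
    grads: dict[str, np.ndarray] = {}
    dsig = 0.5 * (dout + dout.transpose(0, 2, 1))
    dlogits = dsig * sig * (1.0 - sig)
    dy = np.zeros((dout.shape[0], 1, S, S))
    dy[:, 0, :L, :L] = dlogits
    dg, grads["out_w"], grads["out_b"] = conv2d_backward(dy, p["out_w"], out_cache)

    dskips = [None] * (params.n + 1)  # gradient flowing into F_0 .. F_n
    for k in range(params.n, 0, -1):
        up_ch, bc = dec_caches[k - 1]
        dcat = _conv_block_backward(dg, p, f"dec{k}", bc, grads)
        dup, dskip = dcat[:, :up_ch], dcat[:, up_ch:]
        idx = params.n - k
        dskips[idx] = dskip if dskips[idx] is None else dskips[idx] + dskip
        dg = upsample2_backward(dup)
    # dg now flows into F_n
    dfeat = dg
    for k in range(params.n, 0, -1):
        if dskips[k] is not None:
            dfeat = dfeat + dskips[k]
        pc, bc = enc_caches[k - 1]
        dpooled = _conv_block_backward(dfeat, p, f"enc{k}", bc, grads)
        dfeat = maxpool2_backward(dpooled, pc)
    if dskips[0] is not None:
        dfeat = dfeat + dskips[0]
    dC = dfeat[:, 0, :L, :L]
    return grads, dC


def refine(C: np.ndarray, params: RefinementParams) -> np.ndarray:
    """Refine one L x L correlation map; output is L x L, symmetric, in [0,1]."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("expected a square L x L map")
    out, _ = refine_batch(C[None], params)
    return out[0]
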