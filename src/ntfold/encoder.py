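"""Nucleotide attention: embeddings, multi-head self-attention, correlation map.

Each residue is embedded as a learned vector plus a fixed sinusoidal positional
encoding.  Multi-head scaled dot-product attention over the embeddings yields
per-head L x L attention maps; averaging the heads gives the correlation map C,
a row-stochastic matrix whose entry (i, j) measures how strongly nucleotide i
attends to nucleotide j — the model's initial estimate of pairing propensity.

C is deliberately not symmetrised here; symmetry is a structural constraint and
is enforced downstream (refiner output and decoder).

An ablation path replaces attention with a logistic outer-product map computed
from the embeddings alone, so the rest of the pipeline can be exercised without
the attention mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import sigmoid, softmax_rows, softmax_rows_backward
from .structure_io import ALPHABET, RnaSequence

__all__ = [
    "EncoderParams",
    "positional_encoding",
    "embed_sequence",
    "attention_head",
    "correlation_map",
]


@dataclass
class EncoderParams:
    """Trainable tables: embedding E (|V| x d) and per-head d x d_h projections."""

    d: int
    H: int
    params: dict[str, np.ndarray] = field(repr=False)

    def __init__(self, d: int = 64, H: int = 4, params: dict | None = None,
                 rng: np.random.Generator | None = None):
        if H < 1 or d % H != 0:
            raise ValueError("require H >= 1 and d divisible by H (d = H * d_h)")
        if d % 2 != 0:
            raise ValueError("d must be even for the sinusoidal positional encoding")
        self.d, self.H = d, H
        if params is not None:
            self.params = params
        else:
            rng = rng or np.random.default_rng(0)
            dh = self.d_h
            p: dict[str, np.ndarray] = {
                "E": rng.normal(0.0, 0.5, size=(len(ALPHABET), d))
            }
            for h in range(H):
                for name in ("Wq", "Wk", "Wv"):
                    p[f"{name}{h}"] = rng.normal(0.0, d ** -0.5, size=(d, dh))
            self.params = p
        for v in self.params.values():
            if not np.all(np.isfinite(v)):
                raise ValueError("encoder parameters must be finite")

    @property
    def d_h(self) -> int:
        return self.d // self.H


def positional_encoding(L: int, d: int) -> np.ndarray:
    """Fixed sinusoidal positional encoding P (L x d).

    P[i, 2t] = sin(i / 10000^(2t/d)), P[i, 2t+1] = cos(i / 10000^(2t/d)).
    Depends only on (L, d); row i is the same for every sequence length.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if d % 2 != 0:
        raise ValueError("d must be even")
    pos = np.arange(L)[:, None]
    t = np.arange(d // 2)[None, :]
    angle = pos / np.power(10000.0, 2.0 * t / d)
    P = np.empty((L, d))
    P[:, 0::2] = np.sin(angle)
    P[:, 1::2] = np.cos(angle)
    return P


def embed_sequence(seq: RnaSequence, params: EncoderParams) -> np.ndarray:
    """Z = E[x] + P, one row per residue (L x d)."""
    idx = seq.indices()
    return params.params["E"][idx] + positional_encoding(seq.L, params.d)


def attention_head(Z: np.ndarray, W_Q: np.ndarray, W_K: np.ndarray,
                   W_V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One head of scaled dot-product attention.

    Returns (A, context) where A = row-softmax(Q K^T / sqrt(d_h)) is L x L and
    context = A V is L x d_h.
    """
    dh = W_Q.shape[1]
    Q, K, V = Z @ W_Q, Z @ W_K, Z @ W_V
    A = softmax_rows(Q @ K.T / np.sqrt(dh))
    return A, A @ V


def correlation_map(seq: RnaSequence, params: EncoderParams) -> np.ndarray:
    """Head-averaged attention map C = (1/H) sum_h A_h; rows sum to 1."""
    C, _ = _forward_batch(seq.indices()[None, :], params)
    return C[0]


# ---------------------------------------------------------------------------
# batched training path (B sequences of equal length)


def _forward_batch(idx: np.ndarray, params: EncoderParams):
    """Correlation maps for a batch of index arrays (B, L). Returns (C, cache)."""
    p = params.params
    B, L = idx.shape
    P = positional_encoding(L, params.d)
    Z = p["E"][idx] + P  # (B, L, d)
    dh = params.d_h
    heads = []
    C = np.zeros((B, L, L))
    for h in range(params.H):
        Q = Z @ p[f"Wq{h}"]
        K = Z @ p[f"Wk{h}"]
        A = softmax_rows(Q @ K.transpose(0, 2, 1) / np.sqrt(dh))
        heads.append((Q, K, A))
        C += A
    C /= params.H
    return C, (idx, Z, heads)


def _backward_batch(dC: np.ndarray, params: EncoderParams, cache):
    """Gradients of a scalar loss w.r.t. encoder parameters, given dL/dC."""
    p = params.params
    idx, Z, heads = cache
    dh = params.d_h
    scale = 1.0 / np.sqrt(dh)
    dZ = np.zeros_like(Z)
    grads = {k: np.zeros_like(v) for k, v in p.items() if not k.startswith("Wv")}
    dA_common = dC / params.H
    for h, (Q, K, A) in enumerate(heads):
        dS = softmax_rows_backward(dA_common, A) * scale
        dQ = dS @ K
        dK = dS.transpose(0, 2, 1) @ Q
        grads[f"Wq{h}"] = np.einsum("bld,blh->dh", Z, dQ)
        grads[f"Wk{h}"] = np.einsum("bld,blh->dh", Z, dK)
        dZ += dQ @ p[f"Wq{h}"].T + dK @ p[f"Wk{h}"].T
    np.add.at(grads["E"], idx.ravel(), dZ.reshape(-1, params.d))
    return grads


# ---------------------------------------------------------------------------
# ablation: logistic outer-product map from embeddings only


def _forward_batch_no_attention(idx: np.ndarray, params: EncoderParams):
    p = params.params
    B, L = idx.shape
    P = positional_encoding(L, params.d)
    Z = p["E"][idx] + P
    S = Z @ Z.transpose(0, 2, 1) / np.sqrt(params.d)
    C = sigmoid(S)
    return C, (idx, Z, C)


def _backward_batch_no_attention(dC: np.ndarray, params: EncoderParams, cache):
    idx, Z, C = cache
    dS = dC * C * (1.0 - C) / np.sqrt(params.d)
    dZ = (dS + dS.transpose(0, 2, 1)) @ Z
    grads = {"E": np.zeros_like(params.params["E"])}
    np.add.at(grads["E"], idx.ravel(), dZ.reshape(-1, params.d))
    return grads
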