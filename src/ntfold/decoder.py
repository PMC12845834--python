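"""From refined score map to a valid binary contact map.

Three stages:

1. sparsity-aware soft thresholding — multiply each score by a logistic gate
   centred at the threshold s, so weak entries shrink toward zero while strong
   entries pass nearly unchanged;
2. Lagrangian constraint iteration — gradient ascent on the evidence combined
   with a per-nucleotide multiplier that penalises row sums exceeding one
   (each nucleotide pairs with at most one partner), with the iterate clipped,
   masked and symmetrised every step;
3. greedy binarisation — accept candidate cells above the binarisation
   threshold in descending score order, skipping any cell whose endpoints are
   already used.

The binariser, not the relaxation, is what guarantees the hard constraints:
symmetry, pairing exclusivity, mask compliance and a zero diagonal hold for
every output on every input.  A brute-force maximum-weight matching oracle is
provided for verification at small L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import RnaSequence

__all__ = [
    "DecodingConfig",
    "soft_sign",
    "threshold_map",
    "lagrangian_decode",
    "valid_pair_mask",
    "binarize",
    "decode",
    "brute_force_decode",
    "read_score_matrix",
    "write_score_matrix",
]

CANONICAL_PAIRS = frozenset(["AU", "UA", "GC", "CG", "GU", "UG"])


@dataclass(frozen=True)
class DecodingConfig:
    """Knobs for thresholding, the Lagrangian loop, and binarisation.

    s: sparsity threshold; kappa: soft-sign sharpness; eta / eta_lambda: step
    sizes of the descent and multiplier updates; T: iteration budget; min_sep:
    minimum |j - i| for a legal pair (3 unpaired residues between partners);
    canonical_only: restrict pairs to Watson-Crick + wobble; bin_threshold:
    final binarisation cut.
    """

    s: float = 0.5
    kappa: float = 10.0
    eta: float = 0.01
    eta_lambda: float = 0.01
    T: int = 100
    min_sep: int = 4
    canonical_only: bool = False
    bin_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("s must be in [0,1]")
        if self.kappa <= 0 or self.eta <= 0 or self.eta_lambda <= 0:
            raise ValueError("kappa, eta and eta_lambda must be positive")
        if self.T < 1:
            raise ValueError("iteration budget T must be >= 1")
        if self.min_sep < 1:
            raise ValueError("min_sep must be >= 1")
        if not 0.0 < self.bin_threshold < 1.0:
            raise ValueError("bin_threshold must be in (0,1)")


def soft_sign(x, kappa: float):
    """Smooth step 1 / (1 + exp(-kappa x)); monotone, limits 0 and 1."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    x = np.asarray(x, dtype=float)
    z = kappa * x
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if out.ndim else float(out)


def threshold_map(c_refined: np.ndarray, cfg: DecodingConfig) -> np.ndarray:
    """Sparsity-aware thresholding: C~ = soft_sign(C - s) * C elementwise."""
    c_refined = np.asarray(c_refined, dtype=float)
    return soft_sign(c_refined - cfg.s, cfg.kappa) * c_refined


def valid_pair_mask(seq: RnaSequence, cfg: DecodingConfig) -> np.ndarray:
    """Symmetric {0,1} mask of legal pair positions.

    A cell (i, j) is legal iff |i - j| >= min_sep and, when canonical_only is
    set, the residue pair is Watson-Crick or wobble (N never pairs then).
    """
    L = seq.L
    idx = np.arange(L)
    mask = (np.abs(idx[:, None] - idx[None, :]) >= cfg.min_sep).astype(np.int8)
    if cfg.canonical_only:
        ok = np.zeros((L, L), dtype=np.int8)
        for i, a in enumerate(seq.residues):
            for j, b in enumerate(seq.residues):
                if a + b in CANONICAL_PAIRS:
                    ok[i, j] = 1
        mask &= ok
    return mask


def lagrangian_decode(
    c_tilde: np.ndarray, mask: np.ndarray, cfg: DecodingConfig,
    return_violations: bool = False,
):
    """Constraint-aware relaxation of the thresholded score map.

    Iterates T times:  A <- A - eta * G  with
    G = A * (lambda_i * soft_sign(sum_j A_ij - 1) - 0.5 * C~), then clips A to
    [0,1], re-applies the mask, re-symmetrises, and takes the multiplier ascent
    step lambda <- lambda + eta_lambda * relu(sum_j A_ij - 1).  The evidence
    term grows entries supported by C~; the multiplier term shrinks rows that
    exceed one partner.
    """
    c_tilde = np.asarray(c_tilde, dtype=float)
    mask = np.asarray(mask)
    if mask.shape != c_tilde.shape:
        raise ValueError("mask and score map shapes differ")
    if not np.array_equal(mask, mask.T):
        raise ValueError("mask must be symmetric")
    if np.any(c_tilde < 0):
        raise ValueError("thresholded scores must be nonnegative")
    A = c_tilde * mask
    A = 0.5 * (A + A.T)
    lam = np.zeros(A.shape[0])
    violations = []
    for _ in range(cfg.T):
        viol = A.sum(axis=1) - 1.0
        G = A * (lam[:, None] * soft_sign(viol, cfg.kappa)[:, None] - 0.5 * c_tilde)
        A = A - cfg.eta * G
        np.clip(A, 0.0, 1.0, out=A)
        A = A * mask
        A = 0.5 * (A + A.T)
        excess = np.maximum(A.sum(axis=1) - 1.0, 0.0)
        lam = lam + cfg.eta_lambda * excess
        if return_violations:
            violations.append(float(excess.mean()))
    if return_violations:
        return A, violations
    return A


def binarize(A: np.ndarray, mask: np.ndarray, cfg: DecodingConfig) -> np.ndarray:
    """Greedy matching: accept upper-triangle cells with A > bin_threshold and
    mask = 1 in descending score order (ties: smaller i, then smaller j),
    skipping cells whose endpoints are already paired.  The output is a
    symmetric {0,1} map in which every index occurs in at most one pair and
    masked cells are zero.
    """
    A = np.asarray(A, dtype=float)
    L = A.shape[0]
    ii, jj = np.nonzero(np.triu((A > cfg.bin_threshold) & (mask > 0), k=1))
    order = sorted(range(len(ii)), key=lambda k: (-A[ii[k], jj[k]], ii[k], jj[k]))
    used = np.zeros(L, dtype=bool)
    M = np.zeros((L, L), dtype=np.int8)
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if used[i] or used[j]:
            continue
        used[i] = used[j] = True
        M[i, j] = M[j, i] = 1
    return M


def decode(
    c_refined: np.ndarray, seq: RnaSequence, cfg: DecodingConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Full pipeline: threshold -> Lagrangian relaxation -> binarise.

    Returns (M, A): the binary contact map and the relaxed map it was cut from.
    """
    cfg = cfg or DecodingConfig()
    mask = valid_pair_mask(seq, cfg)
    c_tilde = threshold_map(c_refined, cfg)
    A = lagrangian_decode(c_tilde, mask, cfg)
    return binarize(A, mask, cfg), A


def brute_force_decode(
    weights: np.ndarray, mask: np.ndarray, bin_threshold: float
) -> np.ndarray:
    """Exhaustive maximum-total-weight matching over candidate cells.

    Candidates are upper-triangle cells with weight > bin_threshold and
    mask = 1.  All matchings are enumerated (L <= 12 only); ties are broken
    toward the lexicographically smallest sorted pair list.  Test oracle, not
    a production decoder.
    """
    weights = np.asarray(weights, dtype=float)
    L = weights.shape[0]
    if L > 12:
        raise ValueError("brute-force oracle limited to L <= 12")
    ii, jj = np.nonzero(np.triu((weights > bin_threshold) & (np.asarray(mask) > 0), k=1))
    cells = sorted(zip(ii.tolist(), jj.tolist()))
    # suffix sums bound the weight still attainable, for branch-and-bound pruning
    suffix = [0.0] * (len(cells) + 1)
    for k in range(len(cells) - 1, -1, -1):
        suffix[k] = suffix[k + 1] + float(weights[cells[k]])
    best_weight = -1.0
    best_pairs: list[tuple[int, int]] = []

    def rec(pos: int, used: int, total: float, chosen: list[tuple[int, int]]) -> None:
        nonlocal best_weight, best_pairs
        if total + suffix[pos] < best_weight - 1e-12:
            return
        if pos == len(cells):
            if total > best_weight + 1e-12 or (
                abs(total - best_weight) <= 1e-12 and chosen < best_pairs
            ):
                best_weight = total
                best_pairs = list(chosen)
            return
        i, j = cells[pos]
        if not (used >> i & 1) and not (used >> j & 1):
            chosen.append((i, j))
            rec(pos + 1, used | 1 << i | 1 << j, total + weights[i, j], chosen)
            chosen.pop()
        rec(pos + 1, used, total, chosen)

    rec(0, 0, 0.0, [])
    M = np.zeros((L, L), dtype=np.int8)
    for i, j in best_pairs:
        M[i, j] = M[j, i] = 1
    return M


# ---------------------------------------------------------------------------
# standalone score-matrix I/O (for decoding scores produced elsewhere)


def read_score_matrix(text: str) -> np.ndarray:
    """Whitespace/TSV matrix, optionally preceded by a ``# L=<int>`` header."""
    rows = []
    L = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "L=" in line:
                L = int(line.split("L=")[1].split()[0])
            continue
        rows.append([float(v) for v in line.replace(",", " ").split()])
    M = np.array(rows, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("score matrix must be square")
    if L is not None and M.shape[0] != L:
        raise ValueError(f"header says L={L} but matrix is {M.shape[0]}x{M.shape[1]}")
    return M


def write_score_matrix(M: np.ndarray) -> str:
    M = np.asarray(M)
    header = f"# L={M.shape[0]}\n"
    body = "\n".join("\t".join(f"{v:.6g}" for v in row) for row in M)
    return header + body + "\n"
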