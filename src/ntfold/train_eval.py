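"""End-to-end training of encoder + refiner, prediction, and base-pair metrics.

The model is trained to reproduce the true contact map: a weighted binary
cross-entropy over upper-triangle cells with |j - i| >= min_sep compares the
refined map against the 0/1 truth, with paired cells up-weighted to counter
the ~1/L density of positives.  The decoder is untrained post-processing.

Evaluation uses exact base-pair matching: TP is the number of predicted pairs
that appear in the reference, precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 their harmonic mean, with the 0/0 -> 0 convention.  Dataset summaries are
macro-averages (mean of per-sequence metrics).
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ._nn import Adam
from .decoder import DecodingConfig, decode, valid_pair_mask
from .encoder import (
    EncoderParams,
    _backward_batch,
    _backward_batch_no_attention,
    _forward_batch,
    _forward_batch_no_attention,
)
from .refiner import RefinementParams, refine_batch, refine_batch_backward
from .structure_io import (
    RnaSequence,
    SecondaryStructure,
    contact_map_to_structure,
    structure_to_contact_map,
)

__all__ = [
    "TrainConfig",
    "EvalResult",
    "Checkpoint",
    "contact_loss",
    "train",
    "predict",
    "evaluate",
    "evaluate_dataset",
    "save_checkpoint",
    "load_checkpoint",
]

_EPS = 1e-7


@dataclass
class TrainConfig:
    lr: float = 1e-3
    epochs: int = 30
    batch_size: int = 16
    pos_weight: float = 10.0
    seed: int = 0
    min_sep: int = 4
    max_len: int = 512
    no_attention: bool = False
    no_refiner: bool = False

    def __post_init__(self) -> None:
        if self.pos_weight < 1:
            raise ValueError("pos_weight must be >= 1")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass(frozen=True)
class EvalResult:
    TP: int
    FP: int
    FN: int
    precision: float
    recall: float
    f1: float


@dataclass
class Checkpoint:
    encoder: EncoderParams
    refiner: RefinementParams
    train_config: TrainConfig = field(default_factory=TrainConfig)
    loss_history: list[float] = field(default_factory=list)


def _loss_cells(L: int, min_sep: int) -> np.ndarray:
    idx = np.arange(L)
    return np.triu(idx[None, :] - idx[:, None] >= min_sep)


def contact_loss(
    pred: np.ndarray, truth: np.ndarray, pos_weight: float = 1.0, min_sep: int = 4
) -> float:
    """Weighted BCE over upper-triangle cells at legal separation, mean-reduced."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    loss, _ = _loss_and_grad(pred[None], truth[None], pos_weight, min_sep)
    return loss


def _loss_and_grad(pred: np.ndarray, truth: np.ndarray, pos_weight: float,
                   min_sep: int) -> tuple[float, np.ndarray]:
    """Mean weighted BCE over included cells of a batch, and dLoss/dpred."""
    B, L, _ = pred.shape
    cells = _loss_cells(L, min_sep)
    n = int(cells.sum())
    if n == 0:
        return 0.0, np.zeros_like(pred)
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    y = truth
    w = np.where(y > 0.5, pos_weight, 1.0)
    ce = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    loss = float((w * ce * cells).sum() / (B * n))
    dp = np.where(
        (pred > _EPS) & (pred < 1.0 - _EPS),
        w * (p - y) / (p * (1.0 - p)) * cells / (B * n),
        0.0,
    )
    return loss, dp


def _encoder_fns(cfg: TrainConfig):
    if cfg.no_attention:
        return _forward_batch_no_attention, _backward_batch_no_attention
    return _forward_batch, _backward_batch


def _make_batches(
    dataset: list[tuple[RnaSequence, SecondaryStructure]],
    batch_size: int,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group records of equal length into (indices, truth-map) batches."""
    by_len: dict[int, list[tuple[RnaSequence, SecondaryStructure]]] = {}
    for seq, ss in dataset:
        if ss.L != seq.L:
            raise ValueError(f"record {seq.id}: sequence/structure length mismatch")
        by_len.setdefault(seq.L, []).append((seq, ss))
    batches = []
    for L in sorted(by_len):
        group = by_len[L]
        for k in range(0, len(group), batch_size):
            chunk = group[k : k + batch_size]
            idx = np.stack([seq.indices() for seq, _ in chunk])
            truth = np.stack(
                [structure_to_contact_map(ss).astype(float) for _, ss in chunk]
            )
            batches.append((idx, truth))
    return batches


def train(
    dataset: list[tuple[RnaSequence, SecondaryStructure]],
    enc_params: EncoderParams | None = None,
    ref_params: RefinementParams | None = None,
    cfg: TrainConfig | None = None,
    verbose: bool = False,
) -> Checkpoint:
    """Jointly fit encoder and refiner to the true contact maps by Adam on the
    weighted BCE; returns a checkpoint with the per-epoch mean loss history.
    """
    cfg = cfg or TrainConfig()
    if not dataset:
        raise ValueError("dataset is empty")
    for seq, _ in dataset:
        if seq.L > cfg.max_len:
            raise ValueError(f"record {seq.id}: L={seq.L} exceeds max_len={cfg.max_len}")
    rng = np.random.default_rng(cfg.seed)
    enc_params = enc_params or EncoderParams(rng=rng)
    ref_params = ref_params or RefinementParams(identity=cfg.no_refiner, rng=rng)
    if cfg.no_refiner:
        ref_params.identity = True

    enc_fwd, enc_bwd = _encoder_fns(cfg)
    trainable: dict[str, np.ndarray] = {}
    if cfg.no_attention:
        trainable["enc.E"] = enc_params.params["E"]
    else:
        trainable.update(
            {f"enc.{k}": v for k, v in enc_params.params.items()
             if not k.startswith("Wv")}
        )
    if not ref_params.identity:
        trainable.update({f"ref.{k}": v for k, v in ref_params.params.items()})
    opt = Adam(trainable, lr=cfg.lr)

    batches = _make_batches(dataset, cfg.batch_size)
    history: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(batches))
        epoch_loss = 0.0
        n_records = 0
        for b in order:
            idx, truth = batches[b]
            C, enc_cache = enc_fwd(idx, enc_params)
            pred, ref_cache = refine_batch(C, ref_params)
            loss, dpred = _loss_and_grad(pred, truth, cfg.pos_weight, cfg.min_sep)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            ref_grads, dC = refine_batch_backward(dpred, ref_params, ref_cache)
            enc_grads = enc_bwd(dC, enc_params, enc_cache)
            grads = {f"enc.{k}": v for k, v in enc_grads.items()}
            grads.update({f"ref.{k}": v for k, v in ref_grads.items()})
            opt.step({k: g for k, g in grads.items() if k in trainable})
            epoch_loss += loss * idx.shape[0]
            n_records += idx.shape[0]
        history.append(epoch_loss / n_records)
        if verbose:
            print(f"epoch {epoch + 1}/{cfg.epochs}: loss={history[-1]:.4f}")
    return Checkpoint(encoder=enc_params, refiner=ref_params,
                      train_config=cfg, loss_history=history)


def predict_map(seq: RnaSequence, ckpt: Checkpoint) -> np.ndarray:
    """Refined contact-probability map for one sequence (no decoding)."""
    cfg = ckpt.train_config
    if seq.L > cfg.max_len:
        raise ValueError(f"sequence length {seq.L} exceeds configured max {cfg.max_len}")
    enc_fwd, _ = _encoder_fns(cfg)
    C, _ = enc_fwd(seq.indices()[None], ckpt.encoder)
    pred, _ = refine_batch(C, ckpt.refiner)
    return pred[0]


def predict(
    seq: RnaSequence, ckpt: Checkpoint, decode_cfg: DecodingConfig | None = None
) -> tuple[SecondaryStructure, np.ndarray]:
    """Full pipeline: encode -> refine -> threshold -> Lagrangian -> binarise.

    Returns the predicted structure (always satisfying symmetry, exclusivity
    and the legality mask) and the relaxed score map it was cut from.
    """
    decode_cfg = decode_cfg or DecodingConfig()
    pred = predict_map(seq, ckpt)
    M, A = decode(pred, seq, decode_cfg)
    return contact_map_to_structure(M), A


def evaluate(pred: SecondaryStructure, truth: SecondaryStructure) -> EvalResult:
    """Exact-match base-pair precision/recall/F1 with the 0/0 -> 0 convention."""
    if pred.L != truth.L:
        raise ValueError(f"length mismatch: pred L={pred.L}, truth L={truth.L}")
    tp = len(pred.pairs & truth.pairs)
    fp = len(pred.pairs - truth.pairs)
    fn = len(truth.pairs - pred.pairs)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return EvalResult(TP=tp, FP=fp, FN=fn, precision=precision, recall=recall, f1=f1)


def evaluate_dataset(
    records: list[tuple[SecondaryStructure, SecondaryStructure]],
    ids: list[str] | None = None,
) -> tuple[list[EvalResult], dict[str, float]]:
    """Per-record metrics plus the macro-average (mean per-sequence P, R, F1)."""
    if not records:
        raise ValueError("no records to evaluate")
    results = [evaluate(p, t) for p, t in records]
    summary = {
        "precision": float(np.mean([r.precision for r in results])),
        "recall": float(np.mean([r.recall for r in results])),
        "f1": float(np.mean([r.f1 for r in results])),
        "n": len(results),
    }
    return results, summary


def summary_tsv(
    results: list[EvalResult], summary: dict[str, float], ids: list[str] | None = None
) -> str:
    ids = ids or [f"record_{k}" for k in range(len(results))]
    lines = ["id\tTP\tFP\tFN\tprecision\trecall\tf1"]
    for rid, r in zip(ids, results):
        lines.append(
            f"{rid}\t{r.TP}\t{r.FP}\t{r.FN}\t{r.precision:.4f}\t{r.recall:.4f}\t{r.f1:.4f}"
        )
    lines.append(
        "macro_average\t-\t-\t-\t"
        f"{summary['precision']:.4f}\t{summary['recall']:.4f}\t{summary['f1']:.4f}"
    )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# checkpoint container: one binary file, JSON header + parameter arrays


def _config_hash(header: dict) -> str:
    return hashlib.sha256(json.dumps(header, sort_keys=True).encode()).hexdigest()[:16]


def save_checkpoint(ckpt: Checkpoint, path: str) -> None:
    header = {
        "encoder": {"d": ckpt.encoder.d, "H": ckpt.encoder.H},
        "refiner": {
            "n": ckpt.refiner.n,
            "base": ckpt.refiner.base,
            "use_coords": ckpt.refiner.use_coords,
            "identity": ckpt.refiner.identity,
        },
        "train_config": asdict(ckpt.train_config),
        "loss_history": ckpt.loss_history,
    }
    header["hash"] = _config_hash(header)
    arrays = {f"enc.{k}": v for k, v in ckpt.encoder.params.items()}
    arrays.update({f"ref.{k}": v for k, v in ckpt.refiner.params.items()})
    buf = io.BytesIO()
    np.savez(buf, header_json=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **arrays)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def load_checkpoint(path: str) -> Checkpoint:
    with np.load(path) as npz:
        header = json.loads(bytes(npz["header_json"]).decode())
        enc_arrays = {k[4:]: npz[k] for k in npz.files if k.startswith("enc.")}
        ref_arrays = {k[4:]: npz[k] for k in npz.files if k.startswith("ref.")}
    enc = EncoderParams(d=header["encoder"]["d"], H=header["encoder"]["H"],
                        params=enc_arrays)
    ref = RefinementParams(params=ref_arrays, **header["refiner"])
    cfg = TrainConfig(**header["train_config"])
    return Checkpoint(encoder=enc, refiner=ref, train_config=cfg,
                      loss_history=list(header["loss_history"]))
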