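"""Synthetic RNA sequence/structure families for training and testing.

Three topologies cover the structural phenomena a contact-map predictor must
handle: single hairpins (one stem + loop), tRNA-like cloverleafs (a closing
stem around three stem-loops, fully nested), and H-type pseudoknots (two
mutually crossing stems).  Stems are complementary under Watson-Crick pairing
with an optional wobble (G-U) fraction; loops and linkers are uniform random
over {A,C,G,U} so composition alone carries no structural signal.

Sequence-level mutation noise is applied after construction; the labeled
structure is always the pre-mutation truth, which makes the pairing signal
imperfect the way real comparative data is.

Every generated structure satisfies ``j - i >= 4`` for all pairs (loop length
>= 3), so generated truths are reachable by the decoder's default mask.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .structure_io import (
    RnaSequence,
    SecondaryStructure,
    write_bpseq,
    write_fasta,
)

__all__ = [
    "FamilySpec",
    "FAMILIES",
    "sample_hairpin",
    "sample_cloverleaf",
    "sample_pseudoknot",
    "sample_family",
    "make_dataset",
    "write_dataset",
]

_BASES = "ACGU"
_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {"G": "U", "U": "G"}

FAMILIES = ("hairpin", "cloverleaf", "pseudoknot")


def compact_specs(mutation_rate: float = 0.0) -> dict[str, "FamilySpec"]:
    """Per-family specs whose stem/loop/linker ranges keep every generated
    structure at L <= 60 (cloverleaf: 4 stems + 4 linkers; pseudoknot: 2 stems
    + 3 loops), for decoder tests that want mixed topologies at short length."""
    return {
        "hairpin": FamilySpec("hairpin", mutation_rate=mutation_rate),
        "cloverleaf": FamilySpec(
            "cloverleaf", stem_len=(2, 4), loop_len=(3, 5), linker_len=(1, 2),
            mutation_rate=mutation_rate,
        ),
        "pseudoknot": FamilySpec(
            "pseudoknot", stem_len=(3, 8), loop_len=(3, 8),
            mutation_rate=mutation_rate,
        ),
    }


@dataclass(frozen=True)
class FamilySpec:
    """Sampling parameters for one structural family.

    ``stem_len`` and ``loop_len`` are inclusive integer ranges; ``gu_fraction``
    is the per-stem-position probability of a wobble pair; ``mutation_rate``
    is the per-residue probability of a random substitution applied to the
    sequence after construction (the structure label is unaffected).
    """

    family: str = "hairpin"
    stem_len: tuple[int, int] = (4, 10)
    loop_len: tuple[int, int] = (3, 8)
    linker_len: tuple[int, int] = (1, 3)
    gu_fraction: float = 0.1
    mutation_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        for name, (lo, hi) in (
            ("stem_len", self.stem_len),
            ("loop_len", self.loop_len),
            ("linker_len", self.linker_len),
        ):
            if lo > hi or lo < 1:
                raise ValueError(f"{name} range ({lo},{hi}) is empty or non-positive")
        if self.loop_len[0] < 3:
            raise ValueError("minimum loop length must be >= 3 (decoder mask floor)")
        for name, p in (("gu_fraction", self.gu_fraction),
                        ("mutation_rate", self.mutation_rate)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")


def _draw(rng: np.random.Generator, rng_pair: tuple[int, int]) -> int:
    lo, hi = rng_pair
    return int(rng.integers(lo, hi + 1))


def _random_loop(rng: np.random.Generator, m: int) -> list[str]:
    return [_BASES[k] for k in rng.integers(0, 4, size=m)]


def _complementary_stem(
    rng: np.random.Generator, k: int, gu_fraction: float
) -> tuple[list[str], list[str]]:
    """k 5' residues and their k 3' partners (3' side returned 5'->3')."""
    five, three = [], []
    for _ in range(k):
        if rng.random() < gu_fraction:
            a = "G" if rng.random() < 0.5 else "U"
            b = _WOBBLE[a]
        else:
            a = _BASES[int(rng.integers(0, 4))]
            b = _WC[a]
        five.append(a)
        three.append(b)
    return five, three[::-1]


def _mutate(rng: np.random.Generator, residues: list[str], rate: float) -> list[str]:
    if rate <= 0.0:
        return residues
    out = list(residues)
    hits = np.nonzero(rng.random(len(out)) < rate)[0]
    for i in hits:
        out[i] = _BASES[int(rng.integers(0, 4))]
    return out


def _finish(
    rng: np.random.Generator,
    name: str,
    residues: list[str],
    pairs: set[tuple[int, int]],
    spec: FamilySpec,
) -> tuple[RnaSequence, SecondaryStructure]:
    residues = _mutate(rng, residues, spec.mutation_rate)
    seq = RnaSequence(id=name, residues="".join(residues))
    return seq, SecondaryStructure(L=len(residues), pairs=frozenset(pairs))


def sample_hairpin(
    spec: FamilySpec, rng: np.random.Generator
) -> tuple[RnaSequence, SecondaryStructure]:
    """One stem of k pairs closing a loop of m unpaired residues; L = 2k + m."""
    k = _draw(rng, spec.stem_len)
    m = _draw(rng, spec.loop_len)
    five, three = _complementary_stem(rng, k, spec.gu_fraction)
    residues = five + _random_loop(rng, m) + three
    L = 2 * k + m
    pairs = {(i, L - 1 - i) for i in range(k)}
    return _finish(rng, "hairpin", residues, pairs, spec)


def sample_cloverleaf(
    spec: FamilySpec, rng: np.random.Generator
) -> tuple[RnaSequence, SecondaryStructure]:
    """Closing stem around three stem-loops joined by single-stranded linkers.

    The result is fully nested: the closing stem encloses the three arms, and
    arms do not overlap.
    """
    residues: list[str] = []
    pairs: set[tuple[int, int]] = set()

    k0 = _draw(rng, spec.stem_len)
    five0, three0 = _complementary_stem(rng, k0, spec.gu_fraction)
    residues.extend(five0)

    def add_arm() -> None:
        k = _draw(rng, spec.stem_len)
        m = _draw(rng, spec.loop_len)
        five, three = _complementary_stem(rng, k, spec.gu_fraction)
        start = len(residues)
        residues.extend(five + _random_loop(rng, m) + three)
        arm_L = 2 * k + m
        pairs.update((start + i, start + arm_L - 1 - i) for i in range(k))

    residues.extend(_random_loop(rng, _draw(rng, spec.linker_len)))
    for _ in range(3):
        add_arm()
        residues.extend(_random_loop(rng, _draw(rng, spec.linker_len)))
    residues.extend(three0)
    L = len(residues)
    pairs.update((i, L - 1 - i) for i in range(k0))
    return _finish(rng, "cloverleaf", residues, pairs, spec)


def sample_pseudoknot(
    spec: FamilySpec, rng: np.random.Generator
) -> tuple[RnaSequence, SecondaryStructure]:
    """H-type pseudoknot: stem 1 pairs region A with C, stem 2 pairs B with D,
    A < B < C < D along the chain, so every stem-1 pair crosses every stem-2 pair.
    """
    k1 = _draw(rng, spec.stem_len)
    k2 = _draw(rng, spec.stem_len)
    m1 = _draw(rng, spec.loop_len)  # between A and B
    m2 = _draw(rng, spec.loop_len)  # between B and C
    m3 = _draw(rng, spec.loop_len)  # between C and D
    s1_five, s1_three = _complementary_stem(rng, k1, spec.gu_fraction)
    s2_five, s2_three = _complementary_stem(rng, k2, spec.gu_fraction)

    residues = (
        s1_five + _random_loop(rng, m1) + s2_five + _random_loop(rng, m2)
        + s1_three + _random_loop(rng, m3) + s2_three
    )
    a0 = 0
    b0 = k1 + m1
    c0 = b0 + k2 + m2
    d0 = c0 + k1 + m3
    pairs = {(a0 + i, c0 + k1 - 1 - i) for i in range(k1)}
    pairs |= {(b0 + i, d0 + k2 - 1 - i) for i in range(k2)}
    return _finish(rng, "pseudoknot", residues, pairs, spec)


_SAMPLERS = {
    "hairpin": sample_hairpin,
    "cloverleaf": sample_cloverleaf,
    "pseudoknot": sample_pseudoknot,
}


def sample_family(
    family: str, spec: FamilySpec, rng: np.random.Generator
) -> tuple[RnaSequence, SecondaryStructure]:
    if spec.family != family:
        spec = replace(spec, family=family)
    return _SAMPLERS[family](spec, rng)


def make_dataset(
    n: int,
    mix: dict[str, float] | None = None,
    specs: dict[str, FamilySpec] | None = None,
    seed: int = 0,
) -> list[tuple[RnaSequence, SecondaryStructure]]:
    """Draw ``n`` sequence/structure pairs with family proportions ``mix``.

    Deterministic under a fixed seed.  Record ids are ``<family>_<index>``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = dict(mix or {"hairpin": 1.0})
    total = sum(mix.values())
    if total <= 0 or any(w < 0 for w in mix.values()):
        raise ValueError("family weights must be nonnegative and sum > 0")
    for fam in mix:
        if fam not in FAMILIES:
            raise ValueError(f"unknown family {fam!r}")
    specs = specs or {}
    rng = np.random.default_rng(seed)
    families = sorted(mix)
    probs = np.array([mix[f] for f in families]) / total
    out = []
    for idx in range(n):
        fam = families[int(rng.choice(len(families), p=probs))]
        spec = specs.get(fam, FamilySpec(family=fam))
        seq, ss = sample_family(fam, spec, rng)
        seq = RnaSequence(id=f"{fam}_{idx:04d}", residues=seq.residues)
        out.append((seq, ss))
    return out


def write_dataset(
    records: list[tuple[RnaSequence, SecondaryStructure]], out_dir: str | Path
) -> Path:
    """Write numbered FASTA + BPSEQ pairs and a manifest TSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = ["id\tfamily\tL\tn_pairs"]
    for seq, ss in records:
        family = seq.id.rsplit("_", 1)[0]
        (out_dir / f"{seq.id}.fasta").write_text(write_fasta(seq))
        (out_dir / f"{seq.id}.bpseq").write_text(write_bpseq(seq, ss))
        manifest.append(f"{seq.id}\t{family}\t{seq.L}\t{ss.n_pairs}")
    path = out_dir / "manifest.tsv"
    path.write_text("\n".join(manifest) + "\n")
    return path
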