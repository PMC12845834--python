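"""Sequences, secondary structures, and the standard text formats that carry them.

An RNA secondary structure is held in two equivalent views: a set of base-pair
index pairs (:class:`SecondaryStructure`) and a symmetric L x L binary contact
map.  Crossing pairs (pseudoknots) are permitted in both views.  All internal
coordinates are 0-based; CT, BPSEQ and dot-bracket files are 1-based on disk
and conversion happens only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RnaSequence",
    "SecondaryStructure",
    "StructureFormatError",
    "parse_fasta",
    "write_fasta",
    "parse_ct",
    "write_ct",
    "parse_bpseq",
    "write_bpseq",
    "parse_dotbracket",
    "write_dotbracket",
    "structure_to_contact_map",
    "contact_map_to_structure",
]

ALPHABET = "AUGCN"
_INPUT_OK = set("ACGUTN")

#: bracket layers for pseudoknotted dot-bracket strings, lowest layer first
BRACKET_LAYERS = [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")]


class StructureFormatError(ValueError):
    """Raised on malformed FASTA/CT/BPSEQ/dot-bracket input."""


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence over the alphabet {A, U, G, C, N}.

    ``T`` is normalized to ``U`` and lowercase is uppercased at construction;
    any other character is rejected.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        raw = self.residues.upper().replace("T", "U")
        for pos, ch in enumerate(raw):
            if ch not in ALPHABET:
                raise StructureFormatError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {pos}"
                )
        if len(raw) < 1:
            raise StructureFormatError(f"record {self.id!r}: empty sequence")
        object.__setattr__(self, "residues", raw)

    @property
    def L(self) -> int:
        return len(self.residues)

    def indices(self) -> np.ndarray:
        """Residues as integer codes into the alphabet A,U,G,C,N."""
        return np.fromiter(
            (ALPHABET.index(c) for c in self.residues), dtype=np.int64, count=self.L
        )


@dataclass(frozen=True)
class SecondaryStructure:
    """A set of base pairs over ``L`` positions, pseudoknots allowed.

    Pairs are stored 0-based with ``i < j``; each index may appear in at most
    one pair (pairing exclusivity).
    """

    L: int
    pairs: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        norm = frozenset((min(i, j), max(i, j)) for i, j in self.pairs)
        seen: set[int] = set()
        for i, j in norm:
            if i == j:
                raise ValueError(f"self-pairing at index {i}")
            if not (0 <= i < j < self.L):
                raise ValueError(f"pair ({i},{j}) out of range for L={self.L}")
            for k in (i, j):
                if k in seen:
                    raise ValueError(f"index {k} appears in more than one pair")
                seen.add(k)
        object.__setattr__(self, "pairs", norm)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def partner_array(self) -> np.ndarray:
        """Length-L array with the partner index of each position, -1 if unpaired."""
        p = np.full(self.L, -1, dtype=np.int64)
        for i, j in self.pairs:
            p[i], p[j] = j, i
        return p

    def is_nested(self) -> bool:
        """True iff no two pairs cross (no pseudoknot)."""
        ordered = sorted(self.pairs)
        for a, (i, j) in enumerate(ordered):
            for k, l in ordered[a + 1 :]:
                if k >= j:
                    break
                if i < k < j < l:
                    return False
        return True


# ---------------------------------------------------------------------------
# FASTA


def parse_fasta(text: str) -> list[RnaSequence]:
    """Parse multi-record FASTA text into validated sequences."""
    records: list[RnaSequence] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        records.append(RnaSequence(id=header, residues=seq))

    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            if not header:
                raise StructureFormatError(f"line {lineno}: empty FASTA header")
            chunks = []
        else:
            if header is None:
                raise StructureFormatError(
                    f"line {lineno}: sequence data before any FASTA header"
                )
            chunks.append(line)
    flush()
    return records


def write_fasta(seqs: list[RnaSequence] | RnaSequence) -> str:
    if isinstance(seqs, RnaSequence):
        seqs = [seqs]
    return "".join(f">{s.id}\n{s.residues}\n" for s in seqs)


# ---------------------------------------------------------------------------
# CT (6-column) and BPSEQ (3-column)


def _check_reciprocal(partner: list[int], fmt: str) -> None:
    for i, j in enumerate(partner):
        if j < 0:
            continue
        if j == i:
            raise StructureFormatError(f"{fmt}: residue {i + 1} pairs with itself")
        if not (0 <= j < len(partner)) or partner[j] != i:
            raise StructureFormatError(
                f"{fmt}: non-reciprocal pairing {i + 1} -> {j + 1}"
            )


def _pairs_from_partner(partner: list[int]) -> frozenset[tuple[int, int]]:
    return frozenset((i, j) for i, j in enumerate(partner) if 0 <= i < j)


def parse_ct(text: str) -> tuple[RnaSequence, SecondaryStructure]:
    """Parse a 6-column CT file (1-based: index, base, prev, next, pair, index)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise StructureFormatError("CT: empty input")
    head = lines[0].split()
    try:
        L = int(head[0])
    except (ValueError, IndexError):
        raise StructureFormatError("CT: first line must begin with the length") from None
    title = " ".join(head[1:]) if len(head) > 1 else "ct"
    body = lines[1:]
    if len(body) != L:
        raise StructureFormatError(f"CT: header says L={L} but found {len(body)} rows")
    residues = []
    partner = [-1] * L
    for row_no, line in enumerate(body, start=1):
        cols = line.split()
        if len(cols) < 6:
            raise StructureFormatError(f"CT: row {row_no} has fewer than 6 columns")
        idx, base, pair_col = int(cols[0]), cols[1], int(cols[4])
        if idx != row_no:
            raise StructureFormatError(f"CT: row {row_no} has index {idx}")
        residues.append(base)
        partner[row_no - 1] = pair_col - 1 if pair_col > 0 else -1
    _check_reciprocal(partner, "CT")
    seq = RnaSequence(id=title, residues="".join(residues))
    return seq, SecondaryStructure(L=L, pairs=_pairs_from_partner(partner))


def write_ct(seq: RnaSequence, ss: SecondaryStructure) -> str:
    if ss.L != seq.L:
        raise ValueError(f"length mismatch: sequence L={seq.L}, structure L={ss.L}")
    partner = ss.partner_array()
    out = [f"{seq.L} {seq.id}"]
    for i in range(seq.L):
        pair = int(partner[i]) + 1 if partner[i] >= 0 else 0
        nxt = i + 2 if i + 1 < seq.L else 0
        out.append(f"{i + 1} {seq.residues[i]} {i} {nxt} {pair} {i + 1}")
    return "\n".join(out) + "\n"


def parse_bpseq(text: str) -> tuple[RnaSequence, SecondaryStructure]:
    """Parse 3-column BPSEQ (1-based: index, base, pair-or-0). ``#`` lines are comments."""
    rows: list[tuple[int, str, int]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) != 3:
            raise StructureFormatError(f"BPSEQ: expected 3 columns, got {line!r}")
        rows.append((int(cols[0]), cols[1], int(cols[2])))
    if not rows:
        raise StructureFormatError("BPSEQ: empty input")
    L = len(rows)
    residues = []
    partner = [-1] * L
    for row_no, (idx, base, pair_col) in enumerate(rows, start=1):
        if idx != row_no:
            raise StructureFormatError(f"BPSEQ: row {row_no} has index {idx}")
        if not (0 <= pair_col <= L):
            raise StructureFormatError(f"BPSEQ: row {row_no} pair index {pair_col} out of range")
        residues.append(base)
        partner[row_no - 1] = pair_col - 1 if pair_col > 0 else -1
    _check_reciprocal(partner, "BPSEQ")
    seq = RnaSequence(id="bpseq", residues="".join(residues))
    return seq, SecondaryStructure(L=L, pairs=_pairs_from_partner(partner))


def write_bpseq(seq: RnaSequence, ss: SecondaryStructure) -> str:
    if ss.L != seq.L:
        raise ValueError(f"length mismatch: sequence L={seq.L}, structure L={ss.L}")
    partner = ss.partner_array()
    lines = [
        f"{i + 1} {seq.residues[i]} {int(partner[i]) + 1 if partner[i] >= 0 else 0}"
        for i in range(seq.L)
    ]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Dot-bracket with pseudoknot layers


def parse_dotbracket(line: str) -> SecondaryStructure:
    """Parse one dot-bracket line; each bracket layer gets its own stack.

    Layers ``()``, ``[]``, ``{}``, ``<>`` in order; ``.`` is unpaired.
    """
    line = line.strip()
    if not line:
        raise StructureFormatError("dot-bracket: empty line")
    opens = {o: k for k, (o, _) in enumerate(BRACKET_LAYERS)}
    closes = {c: k for k, (_, c) in enumerate(BRACKET_LAYERS)}
    stacks: list[list[int]] = [[] for _ in BRACKET_LAYERS]
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(line):
        if ch == ".":
            continue
        if ch in opens:
            stacks[opens[ch]].append(pos)
        elif ch in closes:
            layer = closes[ch]
            if not stacks[layer]:
                raise StructureFormatError(
                    f"dot-bracket: unmatched {ch!r} (layer {layer}) at position {pos}"
                )
            pairs.add((stacks[layer].pop(), pos))
        else:
            raise StructureFormatError(
                f"dot-bracket: illegal character {ch!r} at position {pos}"
            )
    for layer, stack in enumerate(stacks):
        if stack:
            raise StructureFormatError(
                f"dot-bracket: unclosed {BRACKET_LAYERS[layer][0]!r} "
                f"(layer {layer}) at position {stack[-1]}"
            )
    return SecondaryStructure(L=len(line), pairs=frozenset(pairs))


def write_dotbracket(ss: SecondaryStructure) -> str:
    """Write a dot-bracket line, assigning each pair greedily to the lowest
    layer where it does not cross a pair already placed in that layer.

    Pairs are processed in ascending ``i``.  Structures needing more than
    four layers are rejected.
    """
    layer_pairs: list[list[tuple[int, int]]] = [[] for _ in BRACKET_LAYERS]
    for i, j in sorted(ss.pairs):
        for layer, placed in enumerate(layer_pairs):
            if all(not (k < i < l < j or i < k < j < l) for k, l in placed):
                placed.append((i, j))
                break
        else:
            raise ValueError(
                f"structure requires more than {len(BRACKET_LAYERS)} bracket layers"
            )
    chars = ["."] * ss.L
    for layer, placed in enumerate(layer_pairs):
        o, c = BRACKET_LAYERS[layer]
        for i, j in placed:
            chars[i], chars[j] = o, c
    return "".join(chars)


# ---------------------------------------------------------------------------
# pair-list <-> contact-matrix conversion


def structure_to_contact_map(ss: SecondaryStructure) -> np.ndarray:
    """Symmetric L x L {0,1} matrix with 1 at (i,j) and (j,i) for each pair."""
    M = np.zeros((ss.L, ss.L), dtype=np.int8)
    for i, j in ss.pairs:
        M[i, j] = M[j, i] = 1
    return M


def contact_map_to_structure(M: np.ndarray) -> SecondaryStructure:
    """Inverse of :func:`structure_to_contact_map`; validates the map invariants."""
    M = np.asarray(M)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("contact map must be square")
    if not np.array_equal(M, M.T):
        raise ValueError("contact map must be symmetric")
    ii, jj = np.nonzero(np.triu(M, k=1))
    return SecondaryStructure(
        L=M.shape[0], pairs=frozenset(zip(ii.tolist(), jj.tolist()))
    )
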