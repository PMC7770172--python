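"""Sequence and structure domain types, file formats, and pseudoknot detection.

An RNA secondary structure is represented as a set of base pairs ``(i, j)``
with ``i < j`` (0-based), equivalently as a symmetric N x N 0/1 pairing matrix
with zero diagonal and row sums at most one.  The matrix view represents
pseudoknotted (crossing) structures just as naturally as nested ones, which is
the point of using it instead of single-tier dot-bracket strings.

All on-disk formats (BPSEQ, CT, dot-bracket) use 1-based indices; conversion
to the internal 0-based convention happens only at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ALPHABET = "AUCG"
#: Table of one-hot rows; unknown base N maps to the all-zero row.
ONE_HOT_ROWS = {
    "A": (1, 0, 0, 0),
    "U": (0, 1, 0, 0),
    "C": (0, 0, 1, 0),
    "G": (0, 0, 0, 1),
    "N": (0, 0, 0, 0),
}

#: Bracket tiers for pseudoknotted dot-bracket strings (opening, closing).
BRACKET_TIERS = [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")] + [
    (chr(ord("A") + k), chr(ord("a") + k)) for k in range(26)
]


class RnaIOError(ValueError):
    """Malformed sequence or structure input."""


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence over the alphabet {A, U, C, G, N}."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise RnaIOError(f"empty sequence {self.id!r}")
        bad = set(self.bases) - set("AUCGN")
        if bad:
            raise RnaIOError(f"invalid bases {sorted(bad)} in {self.id!r}")

    def __len__(self) -> int:
        return len(self.bases)


def parse_sequence(text: str, id: str = "seq") -> RnaSequence:
    """Normalize raw text into an :class:`RnaSequence`.

    Uppercases, maps DNA-style T to U, and maps any other unknown character
    to N (with a logged warning), mirroring the one-hot table's explicit
    all-zero N row.
    """
    raw = "".join(text.split()).upper()
    if not raw:
        raise RnaIOError("empty sequence input")
    raw = raw.replace("T", "U")
    unknown = sorted(set(raw) - set("AUCGN"))
    if unknown:
        logger.warning("sequence %r: unknown characters %s mapped to N", id, unknown)
        raw = "".join(c if c in "AUCGN" else "N" for c in raw)
    return RnaSequence(id=id, bases=raw)


def one_hot(seq: RnaSequence) -> np.ndarray:
    """N x 4 one-hot encoding (row order A, U, C, G; N encodes as all zeros)."""
    return np.array([ONE_HOT_ROWS[b] for b in seq.bases], dtype=float)


@dataclass(frozen=True)
class SecondaryStructure:
    """A set of base pairs plus the sequence length.

    Each position may appear in at most one pair (one partner per base);
    this is validated at construction.  The ``matrix`` view is the symmetric
    0/1 pairing matrix.
    """

    pairs: frozenset = field(default_factory=frozenset)
    length: int = 0

    def __post_init__(self) -> None:
        norm = frozenset((min(i, j), max(i, j)) for i, j in self.pairs)
        object.__setattr__(self, "pairs", norm)
        seen: set[int] = set()
        for i, j in sorted(norm):
            if i == j:
                raise RnaIOError(f"self-pair at position {i}")
            if not (0 <= i < self.length and 0 <= j < self.length):
                raise RnaIOError(f"pair ({i},{j}) outside length {self.length}")
            for k in (i, j):
                if k in seen:
                    raise RnaIOError(f"position {k} paired more than once")
                seen.add(k)

    def matrix(self) -> np.ndarray:
        return pairs_to_matrix(self.pairs, self.length)

    def sorted_pairs(self) -> list[tuple[int, int]]:
        return sorted(self.pairs)

    def paired_positions(self) -> set[int]:
        out: set[int] = set()
        for i, j in self.pairs:
            out.add(i)
            out.add(j)
        return out


def pairs_to_matrix(pairs: Iterable[tuple[int, int]], n: int) -> np.ndarray:
    """Symmetric N x N 0/1 pairing matrix from a pair set.

    Raises on any index repeated across pairs (one partner per base).
    """
    m = np.zeros((n, n), dtype=int)
    seen: set[int] = set()
    for i, j in sorted((min(p), max(p)) for p in pairs):
        if i == j:
            raise RnaIOError(f"self-pair at position {i}")
        if i < 0 or j >= n:
            raise RnaIOError(f"pair ({i},{j}) outside length {n}")
        for k in (i, j):
            if k in seen:
                raise RnaIOError(f"position {k} paired more than once")
            seen.add(k)
        m[i, j] = m[j, i] = 1
    return m


def matrix_to_pairs(matrix: np.ndarray) -> frozenset:
    """Inverse of :func:`pairs_to_matrix`; validates symmetry and row sums."""
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise RnaIOError(f"pairing matrix must be square, got {m.shape}")
    if not np.array_equal(m, m.T):
        raise RnaIOError("pairing matrix is not symmetric")
    if np.any(np.diag(m) != 0):
        raise RnaIOError("pairing matrix has nonzero diagonal")
    if np.any(m.sum(axis=1) > 1):
        rows = np.nonzero(m.sum(axis=1) > 1)[0]
        raise RnaIOError(f"rows {rows.tolist()} have more than one partner")
    ii, jj = np.nonzero(np.triu(m))
    return frozenset(zip(ii.tolist(), jj.tolist()))


def structure_from_matrix(matrix: np.ndarray) -> SecondaryStructure:
    return SecondaryStructure(matrix_to_pairs(matrix), len(matrix))


# ---------------------------------------------------------------------------
# pseudoknot detection

def detect_pseudoknots(struct: SecondaryStructure):
    """Return ``(flag, crossings)`` where crossings lists every pair of pairs
    ``((i,j),(k,l))`` with ``i < k < j < l`` — the standard crossing criterion
    defining a pseudoknot."""
    ps = struct.sorted_pairs()
    crossings = []
    for a in range(len(ps)):
        i, j = ps[a]
        for b in range(a + 1, len(ps)):
            k, l = ps[b]
            if i < k < j < l:
                crossings.append(((i, j), (k, l)))
    return bool(crossings), crossings


# ---------------------------------------------------------------------------
# dot-bracket

def to_dotbracket(struct: SecondaryStructure) -> str:
    """Extended dot-bracket string; crossing pairs go to higher bracket tiers.

    Pairs are assigned greedily by ascending opening index to the lowest tier
    in which they cross no pair already placed in that tier.
    """
    chars = ["."] * struct.length
    tiers: list[list[tuple[int, int]]] = []
    for i, j in struct.sorted_pairs():
        placed = False
        for t, tier in enumerate(tiers):
            if all(not (k < i < l < j or i < k < j < l) for k, l in tier):
                tier.append((i, j))
                o, c = BRACKET_TIERS[t]
                chars[i], chars[j] = o, c
                placed = True
                break
        if not placed:
            if len(tiers) >= len(BRACKET_TIERS):
                raise RnaIOError(
                    f"structure needs more than {len(BRACKET_TIERS)} bracket tiers"
                )
            tiers.append([(i, j)])
            o, c = BRACKET_TIERS[len(tiers) - 1]
            chars[i], chars[j] = o, c
    return "".join(chars)


def from_dotbracket(text: str) -> SecondaryStructure:
    """Parse (extended) dot-bracket notation into a structure.

    Accepts any of the supported bracket tiers; '.' (and '-'/',') mean
    unpaired.  The parser does not enforce the minimum-loop rule: it reads
    labels as written (``"(.)"`` parses to ``{(0, 2)}``).
    """
    opens = {o: t for t, (o, _) in enumerate(BRACKET_TIERS)}
    closes = {c: t for t, (_, c) in enumerate(BRACKET_TIERS)}
    stacks: dict[int, list[int]] = {}
    pairs = set()
    for pos, ch in enumerate(text):
        if ch in ".,-_:":
            continue
        if ch in opens:
            stacks.setdefault(opens[ch], []).append(pos)
        elif ch in closes:
            t = closes[ch]
            if not stacks.get(t):
                raise RnaIOError(f"unbalanced {ch!r} at position {pos}")
            pairs.add((stacks[t].pop(), pos))
        else:
            raise RnaIOError(f"unknown structure character {ch!r} at position {pos}")
    for t, st in stacks.items():
        if st:
            raise RnaIOError(f"unclosed {BRACKET_TIERS[t][0]!r} at position {st[-1]}")
    return SecondaryStructure(frozenset(pairs), len(text))


# ---------------------------------------------------------------------------
# BPSEQ / CT

def _check_partners(partner: dict[int, int], path: str) -> None:
    for i, j in partner.items():
        if j == 0:
            continue
        if partner.get(j, -1) != i:
            raise RnaIOError(f"{path}: positions {i} and {j} disagree on pairing")


def read_bpseq(path) -> tuple[RnaSequence, SecondaryStructure]:
    """Read a BPSEQ file: lines of ``index base partner`` (1-based, 0 = unpaired)."""
    path = Path(path)
    bases: list[str] = []
    partner: dict[int, int] = {}
    expect = 1
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 3:
                raise RnaIOError(f"{path}:{ln}: expected 3 fields, got {len(fields)}")
            idx, base, par = int(fields[0]), fields[1], int(fields[2])
            if idx != expect:
                raise RnaIOError(f"{path}:{ln}: index {idx}, expected {expect}")
            expect += 1
            bases.append(base)
            partner[idx] = par
    if not bases:
        raise RnaIOError(f"{path}: no records")
    _check_partners(partner, str(path))
    seq = parse_sequence("".join(bases), id=path.stem)
    pairs = frozenset(
        (i - 1, j - 1) for i, j in partner.items() if j > i
    )
    return seq, SecondaryStructure(pairs, len(seq))


def write_bpseq(path, seq: RnaSequence, struct: SecondaryStructure) -> None:
    partner = {i: 0 for i in range(len(seq))}
    for i, j in struct.pairs:
        partner[i], partner[j] = j + 1, i + 1
    with open(path, "w") as fh:
        for i, b in enumerate(seq.bases):
            fh.write(f"{i + 1} {b} {partner[i]}\n")


def read_ct(path) -> tuple[RnaSequence, SecondaryStructure]:
    """Read a CT file (header line, then ``i base i-1 i+1 partner i``)."""
    path = Path(path)
    with open(path) as fh:
        lines = [l.strip() for l in fh if l.strip() and not l.startswith("#")]
    if not lines:
        raise RnaIOError(f"{path}: empty file")
    header = lines[0].split()
    try:
        n = int(header[0])
    except (ValueError, IndexError):
        raise RnaIOError(f"{path}:1: CT header must start with the length") from None
    if len(lines) - 1 != n:
        raise RnaIOError(f"{path}: header says {n} bases, found {len(lines) - 1}")
    bases: list[str] = []
    partner: dict[int, int] = {}
    for ln, line in enumerate(lines[1:], 2):
        fields = line.split()
        if len(fields) < 6:
            raise RnaIOError(f"{path}:{ln}: expected 6 CT columns")
        idx, base, par = int(fields[0]), fields[1], int(fields[4])
        if idx != ln - 1:
            raise RnaIOError(f"{path}:{ln}: index {idx}, expected {ln - 1}")
        bases.append(base)
        partner[idx] = par
    _check_partners(partner, str(path))
    seq = parse_sequence("".join(bases), id=path.stem)
    pairs = frozenset((i - 1, j - 1) for i, j in partner.items() if j > i)
    return seq, SecondaryStructure(pairs, len(seq))


def write_ct(path, seq: RnaSequence, struct: SecondaryStructure) -> None:
    n = len(seq)
    partner = {i: 0 for i in range(n)}
    for i, j in struct.pairs:
        partner[i], partner[j] = j + 1, i + 1
    with open(path, "w") as fh:
        fh.write(f"{n} {seq.id}\n")
        for i, b in enumerate(seq.bases):
            fh.write(f"{i + 1} {b} {i} {i + 2 if i + 1 < n else 0} {partner[i]} {i + 1}\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[RnaSequence]:
    return [
        parse_sequence(str(rec.seq), id=rec.id) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(path, seqs: Sequence[RnaSequence]) -> None:
    records = [
        SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")
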