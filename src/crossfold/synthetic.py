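"""Synthetic RNA sequences, structures, and score matrices for testing.

The generator emits structures obeying the same hard constraints the decoder
enforces — canonical pairs only, hairpin loops of at least 3 unpaired bases,
one partner per base — by recursively placing nested stems (2-6 pairs each)
and, optionally, a single H-type crossing stem that pairs hairpin-loop bases
with unpaired bases downstream to create a pseudoknot.  Sequences are then
sampled so every structural pair is A-U, G-C, or (with probability
``gu_prob``) G-U, and unpaired positions are uniform over A/U/C/G.

This emulates the structural rules of curated RNA corpora at desk scale; it
has no thermodynamics, no family architecture (no tRNA cloverleaf), and no
covariation, so results on it demonstrate algorithmic correctness, not
biological accuracy.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .rna_io import (
    RnaSequence,
    SecondaryStructure,
    detect_pseudoknots,
    write_bpseq,
    write_fasta,
)

MIN_STEM, MAX_STEM = 2, 6
MIN_LOOP = 3


@dataclass
class SynthConfig:
    """Generator settings; defaults give small, desk-scale corpora."""

    n_items: int = 30
    length_range: tuple = (20, 60)
    pk_prob: float = 0.2
    gu_prob: float = 0.2
    noise_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 5:
            raise ValueError("minimum length must be >= 5 (one pair needs |i-j| >= 4)")
        if hi < lo:
            raise ValueError("empty length range")
        for p in (self.pk_prob, self.gu_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_items < 1:
            raise ValueError("need at least one item")


def _fill(lo: int, hi: int, rng: np.random.Generator, pairs: list, depth: int) -> None:
    """Recursively place nested stems in [lo, hi]."""
    span = hi - lo + 1
    if span < 2 * MIN_STEM + MIN_LOOP:
        return
    if depth > 0 and rng.random() < 0.15:
        return  # leave the region unpaired
    if span >= 2 * (2 * MIN_STEM + MIN_LOOP) + 2 and rng.random() < 0.3:
        cut = int(rng.integers(lo + 2 * MIN_STEM + MIN_LOOP - 1, hi - (2 * MIN_STEM + MIN_LOOP) + 1))
        _fill(lo, cut, rng, pairs, depth + 1)
        _fill(cut + 1, hi, rng, pairs, depth + 1)
        return
    slack = span - (2 * MIN_STEM + MIN_LOOP)
    ml = int(rng.integers(0, min(3, slack) + 1))
    mr = int(rng.integers(0, min(3, slack - ml) + 1))
    lmax = min(MAX_STEM, (span - ml - mr - MIN_LOOP) // 2)
    if lmax < MIN_STEM:
        return
    L = int(rng.integers(MIN_STEM, lmax + 1))
    for k in range(L):
        pairs.append((lo + ml + k, hi - mr - k))
    _fill(lo + ml + L, hi - mr - L, rng, pairs, depth + 1)


def _unpaired_runs(paired: set, n: int) -> list[tuple[int, int]]:
    runs, start = [], None
    for i in range(n + 1):
        free = i < n and i not in paired
        if free and start is None:
            start = i
        elif not free and start is not None:
            runs.append((start, i - 1))
            start = None
    return runs


def _add_crossing_stem(pairs: list, n: int, rng: np.random.Generator) -> None:
    """Add one H-type stem pairing loop bases with downstream free bases,
    crossing at least one existing pair; silently does nothing if no room."""
    existing = sorted(pairs)
    paired = {p for ij in existing for p in ij}
    runs = _unpaired_runs(paired, n)
    options = []
    for a_idx in range(len(runs)):
        for b_idx in range(a_idx + 1, len(runs)):
            a_lo, a_hi = runs[a_idx]
            b_lo, b_hi = runs[b_idx]
            lmax = min(a_hi - a_lo + 1, b_hi - b_lo + 1, 3)
            for L in range(lmax, MIN_STEM - 1, -1):
                cand = [(a_lo + k, b_hi - k) for k in range(L)]
                if any(b - a < MIN_LOOP + 1 for a, b in cand):
                    continue
                crosses = all(
                    any(i < a < j < b or a < i < b < j for i, j in existing)
                    for a, b in cand
                )
                if crosses:
                    options.append(cand)
                    break
    if options:
        pairs.extend(options[int(rng.integers(0, len(options)))])


def sample_structure(n: int, pk_prob: float = 0.0,
                     seed: int | None = None,
                     rng: np.random.Generator | None = None) -> SecondaryStructure:
    """Sample a valid structure of length ``n``; deterministic given seed.

    With probability ``pk_prob`` one crossing (H-type) stem is inserted; the
    insertion falls back to a nested structure when no crossing placement
    exists."""
    if n < 5:
        raise ValueError("need n >= 5 for any pair")
    if rng is None:
        rng = np.random.default_rng(seed)
    pairs: list = []
    _fill(0, n - 1, rng, pairs, 0)
    want_pk = rng.random() < pk_prob
    if want_pk and pairs:
        _add_crossing_stem(pairs, n, rng)
    return SecondaryStructure(frozenset(pairs), n)


_PAIR_TYPES = [("A", "U"), ("G", "C")]


def sample_sequence(struct: SecondaryStructure, gu_prob: float = 0.2,
                    seed: int | None = None,
                    rng: np.random.Generator | None = None,
                    id: str = "synth") -> RnaSequence:
    """Sample a sequence realizing the structure with canonical pairs only."""
    if rng is None:
        rng = np.random.default_rng(seed)
    bases = [None] * struct.length
    for i, j in struct.sorted_pairs():
        if rng.random() < gu_prob:
            a, b = ("G", "U")
        else:
            a, b = _PAIR_TYPES[int(rng.integers(0, 2))]
        if rng.random() < 0.5:
            a, b = b, a
        bases[i], bases[j] = a, b
    for i in range(struct.length):
        if bases[i] is None:
            bases[i] = "AUCG"[int(rng.integers(0, 4))]
    return RnaSequence(id=id, bases="".join(bases))


def noisy_score_matrix(struct: SecondaryStructure, noise_sigma: float = 0.0,
                       seed: int | None = None,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Symmetric score matrix: +1 at true pairs, -1 elsewhere, plus noise.

    Noise is drawn i.i.d. on the upper triangle at scale ``noise_sigma`` and
    mirrored so the output stays exactly symmetric."""
    if rng is None:
        rng = np.random.default_rng(seed)
    n = struct.length
    s = 2.0 * struct.matrix() - 1.0
    if noise_sigma > 0:
        noise = rng.normal(0.0, noise_sigma, size=(n, n))
        upper = np.triu(noise, 1)
        s = s + upper + upper.T
    return s


def make_dataset(cfg: SynthConfig, out_dir=None):
    """Generate ``cfg.n_items`` (sequence, structure) examples.

    When ``out_dir`` is given, writes a multi-FASTA, one BPSEQ per record,
    and a JSON manifest recording the config; identical config gives
    byte-identical files."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.length_range
    items = []
    for k in range(cfg.n_items):
        n = int(rng.integers(lo, hi + 1))
        struct = sample_structure(n, cfg.pk_prob, rng=rng)
        seq = sample_sequence(struct, cfg.gu_prob, rng=rng, id=f"synth_{k:04d}")
        items.append((seq, struct))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(out / "sequences.fasta", [s for s, _ in items])
        for seq, struct in items:
            write_bpseq(out / f"{seq.id}.bpseq", seq, struct)
        manifest = {
            "config": {**asdict(cfg), "length_range": list(cfg.length_range)},
            "n_pseudoknotted": sum(detect_pseudoknots(st)[0] for _, st in items),
            "records": [
                {"id": s.id, "length": len(s), "n_pairs": len(st.pairs)}
                for s, st in items
            ],
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return items


def length_histogram(lengths, bins: int = 20):
    """Histogram of sequence lengths: returns (counts, bin_edges)."""
    return np.histogram(np.asarray(list(lengths)), bins=bins)
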