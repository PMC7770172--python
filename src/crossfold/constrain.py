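"""Hard-constraint decoding: turn a score matrix into a valid structure.

Three hard constraints define a valid RNA secondary structure here:

1. only A-U, G-C (Watson-Crick) and G-U (wobble) pairs are allowed;
2. a pair (i, j) needs |i - j| >= 4 (hairpin loops contain >= 3 bases);
3. every base pairs with at most one partner.

Constraints 1-2 are 0/1 masks multiplied into the candidate matrix.
Constraint 3 is relaxed into the penalty ``sum_n relu(rowsum_n - 1)`` and the
decoding objective (to be minimized over the relaxed 0..1 pairing variable a)
is

    -( 1/2 * sum (S - s) * a  -  w * sum relu(rowsum(a) - 1)  -  rho * sum |a| )

optimized by T projected-gradient steps with the box constraint kept by a
sigmoid parameterization, then binarized and cleaned up into an exact
matching.  The decoder is score-agnostic: it works on model outputs and on
user-supplied matrices alike, and crossing (pseudoknotted) pair sets survive
because nothing in the constraints forbids them.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .network import ScoreMatrix
from .rna_io import RnaSequence, SecondaryStructure

_CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
MIN_LOOP = 3  # minimum unpaired bases in a hairpin loop -> |i - j| >= 4


@dataclass(frozen=True)
class ConstraintMasks:
    """The canonical-pair mask (m1) and the minimum-distance mask (m2)."""

    m1: np.ndarray
    m2: np.ndarray

    @property
    def combined(self) -> np.ndarray:
        return self.m1 * self.m2


@dataclass
class DecodeConfig:
    """Decoding hyperparameters.

    ``s`` is the pairing threshold (``S_ij > s`` is required for a pair);
    ``squash`` passes raw scores through a sigmoid first, in which case the
    default threshold 0.5 corresponds to a zero logit.  ``w`` weights the
    one-partner penalty, ``rho`` the L1 sparsity term; ``T`` and ``step`` are
    the gradient-descent iteration count and step size; ``cut`` is the
    binarization level on the relaxed variable.  ``s_matrix`` optionally
    replaces the scalar threshold with a per-cell matrix.
    """

    s: float = 0.5
    w: float = 1.0
    rho: float = 0.01
    T: int = 500
    step: float = 0.2
    cut: float = 0.5
    squash: bool = True
    s_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.T < 1 or self.step <= 0 or self.w < 0 or self.rho < 0:
            raise ValueError("need T >= 1, step > 0, w >= 0, rho >= 0")


def canonical_mask(seq: RnaSequence) -> np.ndarray:
    """Symmetric 0/1 mask of canonically pairable position pairs.

    1 exactly where the unordered base pair is A-U, G-C, or G-U; positions
    holding the unknown base N never pair.
    """
    order = "AUCGN"
    table = np.zeros((5, 5), dtype=int)
    for a, b in _CANONICAL:
        table[order.index(a), order.index(b)] = 1
    idx = np.array([order.index(b) for b in seq.bases])
    return table[idx[:, None], idx[None, :]]


def distance_mask(n: int) -> np.ndarray:
    """Symmetric 0/1 mask; 0 exactly where |i - j| <= MIN_LOOP (incl. diagonal)."""
    if n < 1:
        raise ValueError("length must be >= 1")
    ii = np.arange(n)
    return (np.abs(ii[:, None] - ii[None, :]) > MIN_LOOP).astype(int)


def constraint_masks(seq: RnaSequence) -> ConstraintMasks:
    return ConstraintMasks(canonical_mask(seq), distance_mask(len(seq)))


def pairing_penalty(a: np.ndarray) -> float:
    """sum_n relu(rowsum_n - 1): zero iff every base has at most one partner."""
    rs = np.asarray(a, dtype=float).sum(axis=1)
    return float(np.maximum(rs - 1.0, 0.0).sum())


def _threshold(cfg: DecodeConfig, shape) -> np.ndarray:
    if cfg.s_matrix is not None:
        s = np.asarray(cfg.s_matrix, dtype=float)
        if s.shape != shape:
            raise ValueError(f"threshold matrix shape {s.shape} != scores {shape}")
        return s
    return np.full(shape, cfg.s)


def objective(S: np.ndarray, a: np.ndarray, cfg: DecodeConfig) -> float:
    """The minimized decoding objective at relaxed pairing variable ``a``.

    Lower is better; the fit term rewards mass on above-threshold scores
    while the one-partner and sparsity terms penalize violations.
    """
    S = np.asarray(S, dtype=float)
    a = np.asarray(a, dtype=float)
    s = _threshold(cfg, S.shape)
    fit = 0.5 * float(((S - s) * a).sum())
    return -(fit - cfg.w * pairing_penalty(a) - cfg.rho * float(np.abs(a).sum()))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _conflicts(e: tuple[int, int], at: dict) -> set:
    """Chosen edges sharing an endpoint with e (endpoint -> edge map ``at``)."""
    out = set()
    for p in e:
        c = at.get(p)
        if c is not None and c != e:
            out.add(c)
    return out


def _matching_cleanup(cand: list[tuple[int, int]], margin: np.ndarray,
                      preferred: set, max_moves: int = 500) -> set:
    """Resolve one-to-many conflicts among candidate pairs into a matching.

    Starts from a greedy matching that prefers optimizer-approved cells
    (then higher margin, then lexicographic order) and improves it by
    steepest-ascent local search with single-edge and two-edge swaps until
    no move increases the total pairing margin.
    """
    by_margin = sorted(cand, key=lambda ij: (-margin[ij], ij))
    by_pref = sorted(cand, key=lambda ij: (ij not in preferred, -margin[ij], ij))
    chosen: set = set()
    at: dict[int, tuple[int, int]] = {}

    def place(e):
        chosen.add(e)
        at[e[0]] = at[e[1]] = e

    def remove(e):
        chosen.discard(e)
        for p in e:
            if at.get(p) == e:
                del at[p]

    def refill():
        for f in by_margin:
            if f[0] not in at and f[1] not in at:
                place(f)

    for e in by_pref:
        if e[0] not in at and e[1] not in at:
            place(e)

    tol = 1e-12
    for _ in range(max_moves):
        best_gain, best_move = tol, None
        for e in by_margin:
            if e in chosen:
                continue
            conf = _conflicts(e, at)
            gain = margin[e] - sum(margin[c] for c in conf)
            if gain > best_gain:
                best_gain, best_move = gain, ((e,), conf)
        for c in list(chosen):
            touching = [e for e in by_margin
                        if e not in chosen and (e[0] in c or e[1] in c)][:8]
            for a_i in range(len(touching)):
                e1 = touching[a_i]
                for e2 in touching[a_i + 1:]:
                    if e1[0] in e2 or e1[1] in e2:
                        continue
                    drop = _conflicts(e1, at) | _conflicts(e2, at)
                    gain = margin[e1] + margin[e2] - sum(margin[x] for x in drop)
                    if gain > best_gain:
                        best_gain, best_move = gain, ((e1, e2), drop)
        if best_move is None:
            break
        add, drop = best_move
        for x in drop:
            remove(x)
        for e in add:
            place(e)
        refill()
    return chosen


def constrained_decode(S, seq: RnaSequence, cfg: DecodeConfig | None = None) -> SecondaryStructure:
    """Decode a score matrix into a structure satisfying all hard constraints.

    The relaxed variable is parameterized as ``a = mask * sigmoid(u)`` with
    ``u`` initialized from the (symmetrized) raw scores, stepped ``T`` times
    down the objective gradient (the one-partner penalty weight is annealed
    linearly up to ``w``, the usual penalty-method schedule) and
    re-symmetrized each step.  Cells with ``a > cut`` are the
    optimizer-approved candidates; every above-threshold cell remains a
    candidate pair (the threshold rule: S_ij above s_ij means i and j may
    pair), and a deterministic matching cleanup resolves one-to-many
    conflicts, preferring approved cells.  Deterministic given scores and
    config; degenerate all-banned inputs yield the empty structure.
    """
    cfg = cfg or DecodeConfig()
    raw = S.values if isinstance(S, ScoreMatrix) else np.asarray(S, dtype=float)
    n = len(seq)
    if raw.shape != (n, n):
        raise ValueError(f"score matrix {raw.shape} does not match length {n}")
    raw = 0.5 * (raw + raw.T)
    P = _sigmoid(raw) if cfg.squash else raw
    s = _threshold(cfg, P.shape)
    masks = constraint_masks(seq)
    mask = masks.combined.astype(float)
    if mask.sum() == 0:
        return SecondaryStructure(frozenset(), n)

    u = raw.copy()
    for t in range(cfg.T):
        sig = _sigmoid(u)
        a = mask * sig
        over = (a.sum(axis=1) > 1.0).astype(float)
        w_t = cfg.w * (t + 1) / cfg.T
        grad_a = (
            -0.5 * (P - s)
            + 0.5 * w_t * (over[:, None] + over[None, :])
            + cfg.rho
        )
        u -= cfg.step * grad_a * mask * sig * (1.0 - sig)
        u = 0.5 * (u + u.T)
    a = mask * _sigmoid(u)

    margin = P - s
    cand = [
        (int(i), int(j))
        for i, j in zip(*np.nonzero(np.triu(mask)))
        if margin[i, j] > 0
    ]
    preferred = {e for e in cand if a[e] > cfg.cut}
    pairs = _matching_cleanup(cand, margin, preferred)
    return SecondaryStructure(frozenset(pairs), n)


def brute_force_decode(S, seq: RnaSequence, s: float = 0.0,
                       max_n: int = 14) -> SecondaryStructure:
    """Exact maximizer of ``1/2 sum (S - s) * a`` over valid structures.

    Enumerates matchings over the positive-margin allowed pairs (a pair with
    ``S - s <= 0`` never helps), with branch-and-bound pruning; ties resolved
    toward the lexicographically smallest sorted pair list.  Only intended as
    a verification oracle at small N.
    """
    raw = S.values if isinstance(S, ScoreMatrix) else np.asarray(S, dtype=float)
    n = len(seq)
    if n > max_n:
        raise ValueError(f"brute force limited to N <= {max_n}, got {n}")
    raw = 0.5 * (raw + raw.T)
    mask = constraint_masks(seq).combined
    edges = [
        (i, j, raw[i, j] - s)
        for i, j in combinations(range(n), 2)
        if mask[i, j] and raw[i, j] - s > 0
    ]
    edges.sort(key=lambda e: (e[0], e[1]))
    suffix = np.zeros(len(edges) + 1)
    for k in range(len(edges) - 1, -1, -1):
        suffix[k] = suffix[k + 1] + edges[k][2]

    best_score = 0.0
    best_set: tuple = ()

    tol = 1e-12

    def rec(k: int, used: frozenset, score: float, chosen: tuple) -> None:
        nonlocal best_score, best_set
        if score > best_score + tol:
            best_score, best_set = score, chosen
        elif abs(score - best_score) <= tol and chosen and chosen < best_set:
            best_set = chosen
        if k == len(edges) or score + suffix[k] < best_score - tol:
            return
        i, j, w = edges[k]
        if i not in used and j not in used:
            rec(k + 1, used | {i, j}, score + w, chosen + ((i, j),))
        rec(k + 1, used, score, chosen)

    rec(0, frozenset(), 0.0, ())
    return SecondaryStructure(frozenset(best_set), n)


def load_score_matrix(path) -> np.ndarray:
    """Read a whitespace-delimited N x N score matrix from text.

    Lets the decoder run standalone on scores produced elsewhere; the matrix
    is symmetrized as (S + S^T) / 2 on load."""
    m = np.loadtxt(path, dtype=float, ndmin=2)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: score matrix must be square, got {m.shape}")
    return 0.5 * (m + m.T)


def matching_score(S, struct: SecondaryStructure, s: float = 0.0) -> float:
    """1/2 sum (S - s) * a for the structure's pairing matrix (both triangles)."""
    raw = S.values if isinstance(S, ScoreMatrix) else np.asarray(S, dtype=float)
    return float(sum(raw[i, j] - s for i, j in struct.pairs))


def validate_structure(struct: SecondaryStructure, seq: RnaSequence) -> bool:
    """True iff the structure satisfies all three hard constraints for seq."""
    masks = constraint_masks(seq)
    for i, j in struct.pairs:
        if not masks.m1[i, j] or not masks.m2[i, j]:
            return False
    m = struct.matrix()
    return bool(np.array_equal(m, m.T) and m.sum(axis=1).max(initial=0) <= 1)
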