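"""Input encoding: lift one-hot bases to d dimensions and add position embeddings.

The model input for a length-N sequence is an N x d matrix built in three
steps: (i) a kernel-width-3, same-padded 1-D convolution lifts the N x 4
one-hot matrix to N x d (d > 4); (ii) the absolute positions 1..N and the
relative positions i/N are projected by a learned 2 -> d linear map; (iii) the
two N x d matrices are added elementwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


@dataclass
class PositionEmbedding:
    """Absolute (1..N) and relative (i/N) base positions and their projection."""

    pos_bas: np.ndarray  # (N,), values 1..N
    pos_rel: np.ndarray  # (N,), values i/N
    projected: Tensor    # (N, d)


def position_features(n: int) -> np.ndarray:
    """The raw (N, 2) position matrix [pos_bas, pos_rel]."""
    if n < 1:
        raise ValueError("sequence length must be >= 1")
    bas = np.arange(1, n + 1, dtype=float)
    return np.stack([bas, bas / n], axis=1)


def position_embedding(n: int, d: int, weights: Tensor) -> PositionEmbedding:
    """Project [pos_bas, pos_rel] through a learned 2 x d linear map.

    Deterministic given `weights`; raises for d <= 4 (the feature dimension
    must exceed the 4 one-hot channels).
    """
    if d <= 4:
        raise ValueError(f"feature dimension d must be > 4, got {d}")
    if tuple(weights.shape) != (2, d):
        raise ValueError(f"projection weights must be 2x{d}, got {weights.shape}")
    feats = position_features(n)
    projected = ad.matmul(Tensor(feats), weights)
    return PositionEmbedding(pos_bas=feats[:, 0], pos_rel=feats[:, 1], projected=projected)


def conv1d_same(x: Tensor, weights: Tensor, bias: Tensor | None = None) -> Tensor:
    """Same-padded 1-D convolution over the length axis.

    `x` is (..., N, C_in); `weights` is (k, C_in, C_out) with odd k.
    """
    k = weights.shape[0]
    if k % 2 != 1:
        raise ValueError("kernel width must be odd for same padding")
    n = x.shape[-2]
    p = k // 2
    pad_width = [(0, 0)] * (x.ndim - 2) + [(p, p), (0, 0)]
    xp = ad.pad(x, pad_width)
    out = None
    for o in range(k):
        idx = (Ellipsis, slice(o, o + n), slice(None))
        term = ad.matmul(ad.tslice(xp, idx), ad.tslice(weights, o))
        out = term if out is None else out + term
    if bias is not None:
        out = out + bias
    return out


def lift_encoding(onehot: np.ndarray, weights: Tensor, bias: Tensor | None = None) -> Tensor:
    """Lift an N x 4 one-hot matrix to N x d features (same-length output)."""
    oh = np.asarray(onehot, dtype=float)
    if oh.ndim != 2 or oh.shape[1] != 4:
        raise ValueError(f"one-hot matrix must be Nx4, got {oh.shape}")
    return conv1d_same(Tensor(oh), weights, bias)


def assemble_input(lifted: Tensor, pos: PositionEmbedding) -> Tensor:
    """Elementwise sum of lifted sequence encoding and projected positions."""
    if tuple(lifted.shape) != tuple(pos.projected.shape):
        raise ValueError(
            f"shape mismatch: lifted {lifted.shape} vs positions {pos.projected.shape}"
        )
    return lifted + pos.projected
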