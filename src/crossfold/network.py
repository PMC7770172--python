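"""Encoder-decoder network producing the symmetric base-pair score matrix S.

Architecture: the lifted, position-embedded N x d input passes through a
stack of identical transformer blocks (multi-head self-attention and a
position-wise feed-forward, each with a residual connection followed by layer
normalization).  The per-base hidden states, with the projected positions
added back, are assembled into an N x N pairwise feature map (order-invariant
combination of the i-th and j-th vectors), which three 2-D convolutional
stages (batch-normalized, ReLU between stages) reduce to a single channel.
The output is symmetrized as (M + M^T) / 2.

Variable-length batches are padded to the batch maximum; padded positions are
masked out of attention, normalization statistics, and the loss.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .featurize import conv1d_same, position_features
from .rna_io import RnaSequence, one_hot

_LN_EPS = 1e-5
_BN_EPS = 1e-5


@dataclass
class ModelConfig:
    """Hyperparameters of the encoder-decoder.

    ``d`` is the per-base feature dimension (must exceed the 4 one-hot
    channels and divide evenly into heads); ``conv_channels`` are the three
    decoder stage widths, the last of which must be 1.  ``attention_scale``
    selects the divisor of the attention logits: ``sqrt_d`` (conventional,
    per head) or ``d`` (plain feature-dimension divisor).
    """

    d: int = 64
    n_blocks: int = 3
    n_heads: int = 4
    d_ff: int = 0  # 0 -> 2 * d
    conv_channels: tuple = (32, 16, 1)
    kernel: int = 3
    attention_scale: str = "sqrt_d"
    max_len: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d <= 4:
            raise ValueError("feature dimension d must be > 4")
        if self.n_blocks < 1:
            raise ValueError("need at least one encoder block")
        if self.d % self.n_heads != 0:
            raise ValueError("d must be divisible by n_heads")
        if len(self.conv_channels) != 3 or self.conv_channels[-1] != 1:
            raise ValueError("decoder needs three stages ending in one channel")
        if self.kernel % 2 != 1:
            raise ValueError("decoder kernel must be odd")
        if self.attention_scale not in ("sqrt_d", "d"):
            raise ValueError("attention_scale must be 'sqrt_d' or 'd'")
        if self.d_ff == 0:
            self.d_ff = 2 * self.d

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_channels"] = list(self.conv_channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["conv_channels"] = tuple(d.get("conv_channels", (32, 16, 1)))
        return cls(**d)


@dataclass(frozen=True)
class ScoreMatrix:
    """Symmetric N x N real base-pair score matrix."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"score matrix must be square, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-6):
            raise ValueError("score matrix is not symmetric within 1e-6")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


def attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray,
              scale_mode: str = "sqrt_d") -> tuple[np.ndarray, np.ndarray]:
    """Scaled dot-product attention on plain arrays.

    Returns ``(output, weights)`` where ``weights`` rows are the softmax of
    ``Q K^T / scale``; ``scale`` is sqrt(k) or k per ``scale_mode``.
    """
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    k = Q.shape[-1]
    scale = np.sqrt(k) if scale_mode == "sqrt_d" else float(k)
    logits = Q @ K.T / scale
    logits -= logits.max(axis=-1, keepdims=True)
    w = np.exp(logits)
    w /= w.sum(axis=-1, keepdims=True)
    return w @ V, w


def _layer_norm(x: Tensor, g: Tensor, b: Tensor) -> Tensor:
    m = x.mean(axis=-1, keepdims=True)
    xc = x - m
    v = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * (v + _LN_EPS) ** -0.5 * g + b


def conv2d_same(x: Tensor, weights: Tensor, bias: Tensor) -> Tensor:
    """Same-padded 2-D convolution; x is (B, N, N, C_in), weights (k, k, C_in, C_out)."""
    k = weights.shape[0]
    p = k // 2
    n1, n2 = x.shape[1], x.shape[2]
    xp = ad.pad(x, [(0, 0), (p, p), (p, p), (0, 0)])
    out = None
    for di in range(k):
        for dj in range(k):
            patch = ad.tslice(xp, (slice(None), slice(di, di + n1), slice(dj, dj + n2), slice(None)))
            term = ad.matmul(patch, ad.tslice(weights, (di, dj)))
            out = term if out is None else out + term
    return out + bias


class ScoreModel:
    """The trainable encoder-decoder.  Deterministic given config seed."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.params: dict[str, Tensor] = {}
        d, dff, k = cfg.d, cfg.d_ff, cfg.kernel

        def p(name: str, shape: tuple, fan_in: int, fan_out: int) -> Tensor:
            scale = np.sqrt(2.0 / (fan_in + fan_out))
            t = Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)
            self.params[name] = t
            return t

        def zeros(name: str, shape: tuple) -> Tensor:
            t = Tensor(np.zeros(shape), requires_grad=True)
            self.params[name] = t
            return t

        def ones(name: str, shape: tuple) -> Tensor:
            t = Tensor(np.ones(shape), requires_grad=True)
            self.params[name] = t
            return t

        p("lift_W", (3, 4, d), 12, d)
        zeros("lift_b", (d,))
        p("pos_W", (2, d), 2, d)
        for i in range(cfg.n_blocks):
            for nm in ("Wq", "Wk", "Wv", "Wo"):
                p(f"blk{i}_{nm}", (d, d), d, d)
                zeros(f"blk{i}_{nm}b", (d,))
            ones(f"blk{i}_ln1_g", (d,))
            zeros(f"blk{i}_ln1_b", (d,))
            p(f"blk{i}_ff_W1", (d, dff), d, dff)
            zeros(f"blk{i}_ff_b1", (dff,))
            p(f"blk{i}_ff_W2", (dff, d), dff, d)
            zeros(f"blk{i}_ff_b2", (d,))
            ones(f"blk{i}_ln2_g", (d,))
            zeros(f"blk{i}_ln2_b", (d,))
        chans = (2 * d,) + tuple(cfg.conv_channels)
        for s in range(3):
            cin, cout = chans[s], chans[s + 1]
            p(f"conv{s}_W", (k, k, cin, cout), k * k * cin, cout)
            zeros(f"conv{s}_b", (cout,))
            if s < 2:
                ones(f"bn{s}_g", (cout,))
                zeros(f"bn{s}_b", (cout,))
        # batch-norm running statistics (not trained)
        self.bn_running = {
            f"bn{s}_{nm}": np.zeros(chans[s + 1]) if nm == "mean" else np.ones(chans[s + 1])
            for s in range(2)
            for nm in ("mean", "var")
        }
        self.bn_momentum = 0.1

    # -- pieces -------------------------------------------------------------
    def _mha(self, h: Tensor, i: int, key_bias: np.ndarray) -> Tensor:
        cfg = self.cfg
        B, N = h.shape[0], h.shape[1]
        heads, dh = cfg.n_heads, cfg.d // cfg.n_heads
        P = self.params

        def split(t: Tensor) -> Tensor:
            return ad.transpose(ad.reshape(t, (B, N, heads, dh)), (0, 2, 1, 3))

        q = split(ad.matmul(h, P[f"blk{i}_Wq"]) + P[f"blk{i}_Wqb"])
        kk = split(ad.matmul(h, P[f"blk{i}_Wk"]) + P[f"blk{i}_Wkb"])
        v = split(ad.matmul(h, P[f"blk{i}_Wv"]) + P[f"blk{i}_Wvb"])
        scale = dh ** -0.5 if cfg.attention_scale == "sqrt_d" else 1.0 / dh
        logits = ad.matmul(q, ad.transpose(kk, (0, 1, 3, 2))) * scale + Tensor(key_bias)
        att = ad.softmax(logits, axis=-1)
        ctx = ad.transpose(ad.matmul(att, v), (0, 2, 1, 3))
        ctx = ad.reshape(ctx, (B, N, cfg.d))
        return ad.matmul(ctx, P[f"blk{i}_Wo"]) + P[f"blk{i}_Wob"]

    def encoder_forward(self, x: Tensor, key_bias: np.ndarray) -> Tensor:
        """Apply the transformer block stack to a (B, N, d) input."""
        P = self.params
        h = x
        for i in range(self.cfg.n_blocks):
            h = _layer_norm(h + self._mha(h, i, key_bias),
                            P[f"blk{i}_ln1_g"], P[f"blk{i}_ln1_b"])
            ff = ad.matmul(ad.relu(ad.matmul(h, P[f"blk{i}_ff_W1"]) + P[f"blk{i}_ff_b1"]),
                           P[f"blk{i}_ff_W2"]) + P[f"blk{i}_ff_b2"]
            h = _layer_norm(h + ff, P[f"blk{i}_ln2_g"], P[f"blk{i}_ln2_b"])
        return h

    @staticmethod
    def pairwise_assemble(hidden: Tensor, posproj: Tensor) -> Tensor:
        """(B, N, d) hidden states -> (B, N, N, 2d) symmetric pairwise features.

        The i/j feature is the order-invariant average of the concatenations
        [z_i, z_j] and [z_j, z_i] of z = hidden + projected positions, so
        features(i, j) == features(j, i) by construction.
        """
        z = hidden + posproj
        B, N, d = z.shape
        a = ad.reshape(z, (B, N, 1, d))
        b = ad.reshape(z, (B, 1, N, d))
        m = (a + b) * 0.5
        return ad.concat([m, m], axis=-1)

    def _batch_norm(self, x: Tensor, stage: int, mask4: np.ndarray, training: bool) -> Tensor:
        g, b = self.params[f"bn{stage}_g"], self.params[f"bn{stage}_b"]
        if training:
            cnt = float(mask4.sum())
            mt = Tensor(mask4)
            mean = ad.tsum(x * mt, axis=(0, 1, 2), keepdims=True) * (1.0 / cnt)
            xc = x - mean
            var = ad.tsum(xc * xc * mt, axis=(0, 1, 2), keepdims=True) * (1.0 / cnt)
            mom = self.bn_momentum
            self.bn_running[f"bn{stage}_mean"] = (
                (1 - mom) * self.bn_running[f"bn{stage}_mean"] + mom * mean.data.ravel()
            )
            self.bn_running[f"bn{stage}_var"] = (
                (1 - mom) * self.bn_running[f"bn{stage}_var"] + mom * var.data.ravel()
            )
            return xc * (var + _BN_EPS) ** -0.5 * g + b
        mean = Tensor(self.bn_running[f"bn{stage}_mean"])
        var = Tensor(self.bn_running[f"bn{stage}_var"])
        return (x - mean) * (var + _BN_EPS) ** -0.5 * g + b

    def decoder_forward(self, features: Tensor, mask4: np.ndarray, training: bool = False) -> Tensor:
        """Three convolutional stages -> (B, N, N) symmetric scores."""
        P = self.params
        x = features * Tensor(mask4)
        for s in range(3):
            x = conv2d_same(x, P[f"conv{s}_W"], P[f"conv{s}_b"])
            if s < 2:
                x = ad.relu(self._batch_norm(x, s, mask4, training))
                x = x * Tensor(mask4)
        B, N = x.shape[0], x.shape[1]
        m = ad.reshape(x, (B, N, N))
        return (m + ad.transpose(m, (0, 2, 1))) * 0.5

    # -- end to end ---------------------------------------------------------
    def forward_batch(self, onehots: Sequence[np.ndarray], training: bool = False):
        """Padded batch forward pass.

        Returns ``(scores, mask2d, lengths)``: scores is a (B, N, N) Tensor,
        mask2d the 0/1 valid-cell mask (outer product of the 1-D padding
        masks), lengths the true sequence lengths.
        """
        lengths = [oh.shape[0] for oh in onehots]
        B, N = len(onehots), max(lengths)
        X = np.zeros((B, N, 4))
        pos = np.zeros((B, N, 2))
        mask1 = np.zeros((B, N))
        for b, oh in enumerate(onehots):
            n = lengths[b]
            X[b, :n] = oh
            pos[b, :n] = position_features(n)
            mask1[b, :n] = 1.0
        lifted = conv1d_same(Tensor(X), self.params["lift_W"], self.params["lift_b"])
        posproj = ad.matmul(Tensor(pos), self.params["pos_W"])
        x = lifted + posproj
        key_bias = ((mask1 - 1.0) * 1e9)[:, None, None, :]
        hidden = self.encoder_forward(x, key_bias)
        feats = self.pairwise_assemble(hidden, posproj)
        mask2 = mask1[:, :, None] * mask1[:, None, :]
        scores = self.decoder_forward(feats, mask2[..., None], training=training)
        return scores, mask2, lengths

    def model_forward(self, seq: RnaSequence) -> ScoreMatrix:
        """Score a single sequence (inference mode).

        Raises if the sequence exceeds the configured maximum length (the
        length filter applied throughout: only sequences of length <= max_len
        are modeled).
        """
        if len(seq) > self.cfg.max_len:
            raise ValueError(
                f"sequence {seq.id!r} has length {len(seq)} > max_len {self.cfg.max_len}"
            )
        scores, _, _ = self.forward_batch([one_hot(seq)], training=False)
        return ScoreMatrix(scores.data[0])

    def trainable(self) -> list[Tensor]:
        return list(self.params.values())

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"param_{k}": v.data for k, v in self.params.items()}
        arrays.update({f"running_{k}": v for k, v in self.bn_running.items()})
        np.savez(path, __config__=json.dumps(self.cfg.to_dict()), **arrays)

    @classmethod
    def load(cls, path) -> "ScoreModel":
        with np.load(path, allow_pickle=False) as npz:
            cfg = ModelConfig.from_dict(json.loads(str(npz["__config__"])))
            model = cls(cfg)
            for k in model.params:
                model.params[k].data = npz[f"param_{k}"].astype(float)
            for k in model.bn_running:
                model.bn_running[k] = npz[f"running_{k}"].astype(float)
        return model
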