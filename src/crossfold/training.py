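"""Model training against true pairing matrices, and batch prediction.

The default loss is binary cross-entropy between the sigmoid of the score
matrix and the 0/1 pairing matrix, computed only on cells the hard-constraint
masks allow (banned cells carry no gradient — the decoder zeroes them anyway).
An alternative ``objective_based`` loss evaluates the decoding objective at
the true structure (its one-partner penalty vanishes on any valid reference,
leaving the fit term).  Validation tracks the 2-D F1 of fully decoded
structures, and the best-validation parameters are kept as the final model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .constrain import DecodeConfig, constrained_decode, constraint_masks
from .metrics import MEAN_PER_STRUCTURE, aggregate, count_confusion_2d
from .network import ModelConfig, ScoreModel
from .rna_io import RnaSequence, SecondaryStructure, detect_pseudoknots, one_hot, to_dotbracket

logger = logging.getLogger(__name__)

LOSS_MODES = ("masked_bce", "objective_based")


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 8
    learning_rate: float = 1e-3
    lr_decay: float = 1.0  # per-epoch multiplicative decay ...
    lr_decay_start: int = 0  # ... applied from this epoch on
    seed: int = 0
    loss_mode: str = "masked_bce"
    pos_weight: float = 5.0
    max_len: int = 512
    val_fraction: float = 0.1
    eval_every: int = 10
    early_stop_train_f1: float | None = None
    dedup_val: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("need epochs >= 1 and batch_size >= 1")
        if self.loss_mode not in LOSS_MODES:
            raise ValueError(f"loss_mode must be one of {LOSS_MODES}")


def loss_tensor(scores: Tensor, truths: list[np.ndarray], masks: list[np.ndarray],
                mode: str = "masked_bce", pos_weight: float = 1.0,
                decode_cfg: DecodeConfig | None = None) -> Tensor:
    """Batch loss from padded (B, N, N) scores.

    ``truths``/``masks`` hold each sample's pairing matrix and allowed-cell
    mask at its true length.  ``masked_bce`` averages elementwise BCE over
    allowed cells; ``objective_based`` averages the decoding objective
    evaluated at the truth (fit term only — a valid reference has zero
    one-partner penalty)."""
    B, N = scores.shape[0], scores.shape[1]
    y = np.zeros((B, N, N))
    m = np.zeros((B, N, N))
    for b, (t, mk) in enumerate(zip(truths, masks)):
        n = t.shape[0]
        y[b, :n, :n] = t
        m[b, :n, :n] = mk
    if mode == "masked_bce":
        elem = ad.bce_with_logits(scores, y, pos_weight=pos_weight)
        return ad.masked_mean(elem, m)
    cfg = decode_cfg or DecodeConfig()
    # objective at R = truth: -(1/2 sum (sigma(S) - s) R) per structure
    p = ad.sigmoid(scores) if cfg.squash else scores
    fit = ad.tsum(p * Tensor(y * m)) - Tensor(float((y * m).sum() * cfg.s))
    return fit * (-0.5 / B)


@dataclass
class EpochLog:
    epoch: int
    loss: float
    train_f1: float | None = None
    val_f1: float | None = None


@dataclass
class TrainResult:
    model: ScoreModel
    log: list[EpochLog] = field(default_factory=list)
    best_val_f1: float = 0.0
    best_epoch: int = -1

    def log_frame(self):
        import pandas as pd

        return pd.DataFrame([vars(e) for e in self.log])


def calibrate_batch_norm(model: ScoreModel, items) -> None:
    """Recompute batch-norm running statistics over a full dataset.

    During training the exponential running estimates lag the fast-moving
    batch statistics; one full-dataset pass in training mode replaces them
    with the current exact statistics, which stabilizes decoded-structure
    metrics computed mid-training."""
    saved = model.bn_momentum
    model.bn_momentum = 1.0
    try:
        model.forward_batch([one_hot(s) for s, _ in items], training=True)
    finally:
        model.bn_momentum = saved


def evaluate_f1(model: ScoreModel, items, decode_cfg: DecodeConfig | None = None) -> float:
    """Mean per-structure 2-D F1 of decoded predictions over (seq, struct) items."""
    decode_cfg = decode_cfg or DecodeConfig()
    counts = []
    for seq, truth in items:
        pred = constrained_decode(model.model_forward(seq), seq, decode_cfg)
        counts.append(count_confusion_2d(pred, truth))
    return aggregate(counts, strategy=MEAN_PER_STRUCTURE)["overall"].f1


def train(dataset, model_cfg: ModelConfig | None = None,
          train_cfg: TrainConfig | None = None,
          decode_cfg: DecodeConfig | None = None,
          val_items=None, init_model: ScoreModel | None = None) -> TrainResult:
    """Train a :class:`ScoreModel` on (sequence, structure) pairs.

    The dataset is split into train/validation by ``val_fraction`` unless
    ``val_items`` is passed explicitly; duplicate sequences shared between
    the two splits are dropped from validation when ``dedup_val``.  Batch
    order is shuffled with the config seed each epoch, so runs are exactly
    reproducible.  Aborts on NaN loss."""
    model_cfg = model_cfg or ModelConfig()
    cfg = train_cfg or TrainConfig()
    decode_cfg = decode_cfg or DecodeConfig()
    items = [(s, t) for s, t in dataset if len(s) <= cfg.max_len]
    skipped = len(dataset) - len(items)
    if skipped:
        logger.warning("skipped %d sequences over max_len=%d", skipped, cfg.max_len)
    if not items:
        raise ValueError("no trainable sequences")

    rng = np.random.default_rng(cfg.seed)
    if val_items is None:
        n_val = int(round(cfg.val_fraction * len(items)))
        perm = rng.permutation(len(items))
        val_items = [items[i] for i in perm[:n_val]]
        train_items = [items[i] for i in perm[n_val:]]
        if cfg.dedup_val:
            train_bases = {s.bases for s, _ in train_items}
            val_items = [(s, t) for s, t in val_items if s.bases not in train_bases]
    else:
        train_items = items

    model = init_model if init_model is not None else ScoreModel(model_cfg)
    opt = Adam(model.trainable(), lr=cfg.learning_rate)
    precomp = [
        (one_hot(s), t.matrix().astype(float), constraint_masks(s).combined.astype(float))
        for s, t in train_items
    ]

    result = TrainResult(model=model)
    best_params: dict | None = None
    best_running: dict | None = None
    for epoch in range(1, cfg.epochs + 1):
        opt.lr = cfg.learning_rate * cfg.lr_decay ** max(0, epoch - 1 - cfg.lr_decay_start)
        order = rng.permutation(len(precomp))
        total, nb = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            ohs = [precomp[i][0] for i in idx]
            ys = [precomp[i][1] for i in idx]
            ms = [precomp[i][2] for i in idx]
            scores, _, _ = model.forward_batch(ohs, training=True)
            loss = loss_tensor(scores, ys, ms, mode=cfg.loss_mode,
                               pos_weight=cfg.pos_weight, decode_cfg=decode_cfg)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"loss diverged (non-finite) at epoch {epoch}; "
                    f"last batch sizes {[o.shape[0] for o in ohs]}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item()
            nb += 1

        entry = EpochLog(epoch=epoch, loss=total / max(nb, 1))
        if epoch % cfg.eval_every == 0 or epoch == cfg.epochs:
            calibrate_batch_norm(model, train_items)
            entry.train_f1 = evaluate_f1(model, train_items, decode_cfg)
            if val_items:
                entry.val_f1 = evaluate_f1(model, val_items, decode_cfg)
                if entry.val_f1 >= result.best_val_f1:
                    result.best_val_f1 = entry.val_f1
                    result.best_epoch = epoch
                    best_params = {k: v.data.copy() for k, v in model.params.items()}
                    best_running = {k: v.copy() for k, v in model.bn_running.items()}
        result.log.append(entry)
        logger.info("epoch %d: loss=%.4f train_f1=%s val_f1=%s",
                    epoch, entry.loss, entry.train_f1, entry.val_f1)
        if (cfg.early_stop_train_f1 is not None and entry.train_f1 is not None
                and entry.train_f1 >= cfg.early_stop_train_f1):
            break

    if best_params is not None:
        for k, v in best_params.items():
            model.params[k].data = v
        model.bn_running = best_running
    return result


def predict(model: ScoreModel, sequences, decode_cfg: DecodeConfig | None = None):
    """Decode structures for sequences; over-length ones are skipped with a warning.

    Returns a list of dicts with the sequence, structure, dot-bracket string,
    and pseudoknot flag."""
    decode_cfg = decode_cfg or DecodeConfig()
    out = []
    for seq in sequences:
        if len(seq) > model.cfg.max_len:
            logger.warning("skipping %r: length %d exceeds max_len %d",
                           seq.id, len(seq), model.cfg.max_len)
            continue
        sm = model.model_forward(seq)
        struct = constrained_decode(sm, seq, decode_cfg)
        flag, _ = detect_pseudoknots(struct)
        out.append({
            "sequence": seq,
            "structure": struct,
            "dotbracket": to_dotbracket(struct),
            "pseudoknot": flag,
            "scores": sm,
        })
    return out
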