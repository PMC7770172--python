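"""Structure-comparison metrics: SEN, PPV, and F1 in 2-D and 1-D modes.

The 2-D (matrix) mode compares exact base pairs: a predicted pair counts as
a true positive only when the reference contains the identical (i, j) pair.
The traditional 1-D (vector) mode compares only per-base paired/unpaired
status, ignoring partner identity — it can therefore never score below the
2-D mode on the same prediction, which is exactly why matrix scoring is the
stricter and more truthful benchmark for pseudoknot-capable predictors.

SEN = TP / (TP + FN), PPV = TP / (TP + FP), F1 = harmonic mean of the two.
True negatives are counted but never enter a headline score (unpaired cells
dominate the matrix).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .rna_io import SecondaryStructure

MODE_2D = "matrix2d"
MODE_1D = "vector1d"


@dataclass(frozen=True)
class MetricCounts:
    tp: int
    fn: int
    fp: int
    tn: int
    mode: str = MODE_2D

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("negative confusion count")

    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "MetricCounts") -> "MetricCounts":
        if self.mode != other.mode:
            raise ValueError("cannot pool counts across modes")
        return MetricCounts(self.tp + other.tp, self.fn + other.fn,
                            self.fp + other.fp, self.tn + other.tn, self.mode)


@dataclass(frozen=True)
class MetricReport:
    sen: float
    ppv: float
    f1: float
    mode: str = MODE_2D
    n_structures: int = 1


def count_confusion_2d(pred: SecondaryStructure, truth: SecondaryStructure) -> MetricCounts:
    """Confusion counts over unordered position pairs (i < j), exact-partner."""
    if pred.length != truth.length:
        raise ValueError(f"length mismatch: {pred.length} vs {truth.length}")
    n = pred.length
    tp = len(pred.pairs & truth.pairs)
    fp = len(pred.pairs - truth.pairs)
    fn = len(truth.pairs - pred.pairs)
    cells = n * (n - 1) // 2
    return MetricCounts(tp, fn, fp, cells - tp - fp - fn, MODE_2D)


def count_confusion_1d(pred: SecondaryStructure, truth: SecondaryStructure) -> MetricCounts:
    """Confusion counts over per-base paired/unpaired status (partner ignored)."""
    if pred.length != truth.length:
        raise ValueError(f"length mismatch: {pred.length} vs {truth.length}")
    p, t = pred.paired_positions(), truth.paired_positions()
    tp = len(p & t)
    fp = len(p - t)
    fn = len(t - p)
    return MetricCounts(tp, fn, fp, pred.length - tp - fp - fn, MODE_1D)


def scores(counts: MetricCounts) -> MetricReport:
    """SEN/PPV/F1 from confusion counts.

    Conventions for empty denominators: an empty prediction of an empty
    reference is perfect (all three metrics 1); SEN of an empty reference
    with false positives present is 0; F1 is 0 whenever SEN + PPV is 0.
    """
    tp, fn, fp = counts.tp, counts.fn, counts.fp
    if tp == 0 and fn == 0 and fp == 0:
        return MetricReport(1.0, 1.0, 1.0, counts.mode)
    sen = tp / (tp + fn) if tp + fn > 0 else 0.0
    ppv = tp / (tp + fp) if tp + fp > 0 else 0.0
    f1 = f1_score(sen, ppv)
    return MetricReport(sen, ppv, f1, counts.mode)


def f1_score(sen: float, ppv: float) -> float:
    """Harmonic mean of sensitivity and positive predictive value."""
    return 2.0 * sen * ppv / (sen + ppv) if sen + ppv > 0 else 0.0


MEAN_PER_STRUCTURE = "mean_per_structure"
POOLED_COUNTS = "pooled_counts"


def aggregate(
    counts: Sequence[MetricCounts],
    families: Sequence[str] | None = None,
    strategy: str = MEAN_PER_STRUCTURE,
    known_families: Iterable[str] | None = None,
) -> dict[str, MetricReport]:
    """Per-family and overall metrics.

    ``mean_per_structure`` averages each metric over structures; the reported
    F1 is then the mean of per-structure F1s (not the harmonic mean of the
    averaged SEN/PPV, so the two aggregation strategies genuinely differ).
    ``pooled_counts`` sums confusion counts first and scores once.  Labels
    outside ``known_families`` (when given) group under ``"other"``.
    """
    if not counts:
        raise ValueError("empty evaluation set")
    if strategy not in (MEAN_PER_STRUCTURE, POOLED_COUNTS):
        raise ValueError(f"unknown aggregation strategy {strategy!r}")
    if families is None:
        families = ["all"] * len(counts)
    if len(families) != len(counts):
        raise ValueError("one family label per structure required")
    if known_families is not None:
        known = set(known_families)
        families = [f if f in known else "other" for f in families]

    groups: dict[str, list[MetricCounts]] = {}
    for fam, c in zip(families, counts):
        groups.setdefault(fam, []).append(c)
    groups["overall"] = list(counts)

    out: dict[str, MetricReport] = {}
    for fam, cs in groups.items():
        if strategy == POOLED_COUNTS:
            pooled = cs[0]
            for c in cs[1:]:
                pooled = pooled + c
            rep = scores(pooled)
            out[fam] = MetricReport(rep.sen, rep.ppv, rep.f1, rep.mode, len(cs))
        else:
            reps = [scores(c) for c in cs]
            k = len(reps)
            out[fam] = MetricReport(
                sum(r.sen for r in reps) / k,
                sum(r.ppv for r in reps) / k,
                sum(r.f1 for r in reps) / k,
                reps[0].mode,
                k,
            )
    return out


def report_table(reports: Mapping[str, MetricReport]) -> pd.DataFrame:
    """Tabular view (one row per family) mirroring F1/PPV/SEN benchmark tables."""
    rows = [
        {"family": fam, "f1": r.f1, "ppv": r.ppv, "sen": r.sen,
         "mode": r.mode, "n": r.n_structures}
        for fam, r in sorted(reports.items(), key=lambda kv: (kv[0] == "overall", kv[0]))
    ]
    return pd.DataFrame(rows)


def write_report(reports: Mapping[str, MetricReport], tsv_path=None, json_path=None) -> pd.DataFrame:
    df = report_table(reports)
    if tsv_path is not None:
        df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        df.to_json(json_path, orient="records", indent=2)
    return df
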