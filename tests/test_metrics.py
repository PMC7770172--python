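"""Confusion counting in 2-D and 1-D modes, score formulas, aggregation."""

import numpy as np
import pytest

import crossfold as cf
from crossfold.metrics import (
    MEAN_PER_STRUCTURE,
    POOLED_COUNTS,
    MetricCounts,
    aggregate,
    report_table,
)


def struct(pairs, n):
    return cf.SecondaryStructure(frozenset(pairs), n)


class TestConfusion2d:
    def test_perfect_prediction(self):
        t = struct({(0, 8), (1, 7), (10, 16)}, 20)
        c = cf.count_confusion_2d(t, t)
        assert (c.tp, c.fp, c.fn) == (3, 0, 0)
        assert c.total() == 20 * 19 // 2

    def test_partner_shift_is_double_error(self):
        c = cf.count_confusion_2d(struct({(0, 7)}, 8), struct({(0, 6)}, 8))
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_empty_prediction(self):
        c = cf.count_confusion_2d(struct(set(), 10), struct({(0, 5), (1, 6)}, 10))
        assert (c.tp, c.fn, c.fp) == (0, 2, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cf.count_confusion_2d(struct(set(), 5), struct(set(), 6))


class TestConfusion1d:
    def test_partner_shift_scores_by_status(self):
        c = cf.count_confusion_1d(struct({(0, 7)}, 8), struct({(0, 6)}, 8))
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 5)

    def test_identical_structures(self):
        t = struct({(0, 8), (2, 6)}, 12)
        c = cf.count_confusion_1d(t, t)
        assert c.fp == c.fn == 0 and c.tp == 4


class TestScores:
    def test_formulas(self):
        r = cf.scores(MetricCounts(3, 1, 1, 10))
        assert (r.sen, r.ppv, r.f1) == (0.75, 0.75, 0.75)

    def test_harmonic_mean_matches_published_value(self):
        # a benchmark-table consistency check: F1 from its PPV/SEN
        assert round(cf.f1_score(0.961, 0.972), 3) == 0.966

    def test_empty_vs_empty_is_perfect(self):
        r = cf.scores(MetricCounts(0, 0, 0, 10))
        assert (r.sen, r.ppv, r.f1) == (1.0, 1.0, 1.0)

    def test_empty_truth_with_false_positives(self):
        r = cf.scores(MetricCounts(0, 0, 3, 7))
        assert (r.sen, r.ppv, r.f1) == (0.0, 0.0, 0.0)

    def test_f1_is_harmonic_mean_and_bounded(self, rng):
        for _ in range(200):
            tp, fn, fp = (int(x) for x in rng.integers(0, 10, size=3))
            r = cf.scores(MetricCounts(tp, fn, fp, 5))
            if r.sen + r.ppv > 0:
                assert np.isclose(r.f1, 2 * r.sen * r.ppv / (r.sen + r.ppv))
            assert r.f1 <= (r.sen + r.ppv) / 2 + 1e-12
            assert r.f1 <= 2 * min(r.sen, r.ppv) + 1e-12

    def test_f1_one_iff_exact_match(self, rng):
        for seed in range(20):
            truth = cf.sample_structure(30, 0.3, seed=seed)
            same = cf.scores(cf.count_confusion_2d(truth, truth))
            assert same.f1 == 1.0
            if truth.pairs:
                missing = struct(set(list(truth.pairs)[1:]), 30)
                assert cf.scores(cf.count_confusion_2d(missing, truth)).f1 < 1.0


class TestModeOrdering:
    def test_1d_f1_never_below_2d_f1(self, rng):
        """Partner agreement implies status agreement, never the reverse."""
        for k in range(100):
            n = int(rng.integers(15, 50))
            truth = cf.sample_structure(n, 0.3, rng=rng)
            pred = cf.sample_structure(n, 0.3, rng=rng)
            f2 = cf.scores(cf.count_confusion_2d(pred, truth)).f1
            f1 = cf.scores(cf.count_confusion_1d(pred, truth)).f1
            assert f1 >= f2 - 1e-12


class TestAggregate:
    def test_single_structure_strategies_agree(self):
        c = [cf.count_confusion_2d(struct({(0, 5)}, 10), struct({(0, 5)}, 10))]
        a = aggregate(c, strategy=MEAN_PER_STRUCTURE)["overall"]
        b = aggregate(c, strategy=POOLED_COUNTS)["overall"]
        assert (a.sen, a.ppv, a.f1) == (b.sen, b.ppv, b.f1)

    def test_mean_of_perfect_and_zero(self):
        t = struct({(0, 5), (1, 6)}, 12)
        good = cf.count_confusion_2d(t, t)
        bad = cf.count_confusion_2d(struct({(0, 7), (1, 8)}, 12), t)
        rep = aggregate([good, bad], strategy=MEAN_PER_STRUCTURE)["overall"]
        assert rep.f1 == 0.5

    def test_pooled_equals_scores_of_summed_counts(self, rng):
        counts = [
            cf.count_confusion_2d(cf.sample_structure(20, 0, seed=k),
                                  cf.sample_structure(20, 0, seed=k + 100))
            for k in range(5)
        ]
        total = counts[0]
        for c in counts[1:]:
            total = total + c
        pooled = aggregate(counts, strategy=POOLED_COUNTS)["overall"]
        direct = cf.scores(total)
        assert (pooled.sen, pooled.ppv, pooled.f1) == (direct.sen, direct.ppv, direct.f1)

    def test_unknown_family_grouped_as_other(self):
        c = [cf.count_confusion_2d(struct(set(), 8), struct(set(), 8))] * 3
        reps = aggregate(c, families=["tRNA", "mystery", "tRNA"],
                         known_families=["tRNA", "5S_rRNA"])
        assert set(reps) == {"tRNA", "other", "overall"}
        assert reps["other"].n_structures == 1

    def test_report_table_layout(self):
        c = [cf.count_confusion_2d(struct(set(), 8), struct(set(), 8))]
        df = report_table(aggregate(c, families=["tRNA"]))
        assert list(df.columns) == ["family", "f1", "ppv", "sen", "mode", "n"]
        assert df.iloc[-1]["family"] == "overall"
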