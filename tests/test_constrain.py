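"""Constraint masks, decoding objective, gradient decoder vs brute force."""

import numpy as np
import pytest

import crossfold as cf
from crossfold.constrain import matching_score
from conftest import random_sequence


class TestCanonicalMask:
    def test_gacu_has_six_ones(self):
        m = cf.canonical_mask(cf.parse_sequence("GACU"))
        # allowed: G-C (0,2), G-U (0,3), A-U (1,3) and transposes
        assert m.sum() == 6
        for i, j in [(0, 2), (0, 3), (1, 3)]:
            assert m[i, j] == m[j, i] == 1

    def test_aaaa_all_zero(self):
        assert cf.canonical_mask(cf.parse_sequence("AAAA")).sum() == 0

    def test_n_never_pairs(self):
        m = cf.canonical_mask(cf.parse_sequence("ANAU"))
        assert m[1].sum() == 0 and m[:, 1].sum() == 0


class TestDistanceMask:
    def test_n8_has_20_ones(self):
        assert cf.distance_mask(8).sum() == 20

    def test_n4_all_zero(self):
        assert cf.distance_mask(4).sum() == 0

    def test_diagonal_zero(self):
        for n in (1, 5, 12):
            assert np.all(np.diag(cf.distance_mask(n)) == 0)


class TestPenaltyAndObjective:
    def test_penalty_counts_row_excess(self):
        a = np.zeros((3, 3))
        a[1, 0] = 1.0
        a[2, 0] = a[2, 1] = 1.0  # row sums 0, 1, 2
        assert cf.pairing_penalty(a) == 1.0

    def test_valid_structure_has_zero_penalty(self):
        st = cf.sample_structure(30, 0.3, seed=1)
        assert cf.pairing_penalty(st.matrix()) == 0.0

    def test_all_ones_4x4(self):
        a = np.ones((4, 4)) - np.eye(4)
        assert cf.pairing_penalty(a) == 8.0

    def test_objective_zero_structure(self, rng):
        S = rng.normal(size=(6, 6))
        cfg = cf.DecodeConfig(s=0.0, squash=False)
        assert cf.objective(S, np.zeros((6, 6)), cfg) == 0.0

    def test_objective_single_pair(self):
        S = np.zeros((10, 10))
        S[0, 5] = S[5, 0] = 1.0
        a = np.zeros((10, 10))
        a[0, 5] = a[5, 0] = 1.0
        cfg = cf.DecodeConfig(s=0.0, w=0.0, rho=0.0, squash=False)
        assert np.isclose(cf.objective(S, a, cfg), -1.0)

    def test_overfull_row_worsens_objective(self):
        S = np.zeros((12, 12))
        cfg = cf.DecodeConfig(s=0.0, w=10.0, rho=0.0, squash=False)
        a = np.zeros((12, 12))
        a[0, 5] = a[5, 0] = 1.0
        base = cf.objective(S, a, cfg)
        a2 = a.copy()
        a2[0, 7] = a2[7, 0] = 1.0  # row 0 now sums to 2
        assert cf.objective(S, a2, cfg) > base


def _decode_cfg():
    return cf.DecodeConfig(s=0.0, squash=False, rho=0.0)


class TestConstrainedDecode:
    def test_two_stem_instance_matches_brute_force(self):
        seq = cf.parse_sequence("GGGAAACC", "hairpin")
        S = np.full((8, 8), -1.0)
        for i, j in [(0, 7), (1, 6)]:
            S[i, j] = S[j, i] = 2.0
        dec = cf.constrained_decode(S, seq, _decode_cfg())
        assert dec.pairs == frozenset({(0, 7), (1, 6)})
        assert dec.pairs == cf.brute_force_decode(S, seq).pairs

    def test_all_below_threshold_gives_empty(self, rng):
        seq = random_sequence(rng, 12)
        S = rng.uniform(-1, -0.1, size=(12, 12))
        assert cf.constrained_decode(S, seq, _decode_cfg()).pairs == frozenset()

    def test_short_sequence_distance_banned(self, rng):
        seq = cf.parse_sequence("GAUC")
        S = np.full((4, 4), 5.0)
        assert cf.constrained_decode(S, seq, _decode_cfg()).pairs == frozenset()

    def test_outputs_always_valid(self, rng):
        for k in range(60):
            n = int(rng.integers(20, 80))
            st = cf.sample_structure(n, 0.3, rng=rng)
            seq = cf.sample_sequence(st, rng=rng)
            S = cf.noisy_score_matrix(st, 0.5, rng=rng)
            dec = cf.constrained_decode(S, seq, _decode_cfg())
            assert cf.validate_structure(dec, seq)

    def test_threshold_monotonicity(self):
        st = cf.sample_structure(40, 0.2, seed=9)
        seq = cf.sample_sequence(st, seed=10)
        S = cf.noisy_score_matrix(st, 0.3, seed=11)
        n_pairs = []
        for s in np.linspace(-0.5, 1.5, 9):
            cfg = cf.DecodeConfig(s=float(s), squash=False, rho=0.0)
            n_pairs.append(len(cf.constrained_decode(S, seq, cfg).pairs))
        assert all(a >= b for a, b in zip(n_pairs, n_pairs[1:]))

    def test_pseudoknot_capability(self):
        """A crossing pair set with the only high scores decodes as crossing."""
        st = cf.SecondaryStructure(frozenset({(0, 8), (1, 7), (4, 13), (5, 12)}), 16)
        assert cf.detect_pseudoknots(st)[0]
        seq = cf.sample_sequence(st, seed=3)
        S = cf.noisy_score_matrix(st, 0.0)
        dec = cf.constrained_decode(S, seq, _decode_cfg())
        assert dec.pairs == st.pairs
        assert cf.detect_pseudoknots(dec)[0]


class TestLoadScoreMatrix:
    def test_text_round_trip_symmetrized(self, rng, tmp_path):
        m = rng.normal(size=(6, 6))
        p = tmp_path / "scores.txt"
        np.savetxt(p, m)
        loaded = cf.load_score_matrix(p)
        assert np.allclose(loaded, 0.5 * (m + m.T))

    def test_non_square_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        np.savetxt(p, np.zeros((2, 3)))
        with pytest.raises(ValueError):
            cf.load_score_matrix(p)


class TestBruteForce:
    def test_rejects_large_n(self, rng):
        with pytest.raises(ValueError):
            cf.brute_force_decode(np.zeros((20, 20)), random_sequence(rng, 20))

    def test_empty_when_all_negative(self, rng):
        seq = random_sequence(rng, 10)
        S = rng.uniform(-2, -0.5, size=(10, 10))
        assert cf.brute_force_decode(S, seq).pairs == frozenset()

    def test_conflicting_pairs_pick_heavier(self):
        seq = cf.parse_sequence("GGAAAACCCC")
        S = np.full((10, 10), -1.0)
        S[0, 8] = S[8, 0] = 1.0
        S[0, 9] = S[9, 0] = 2.0  # shares base 0; heavier wins
        assert cf.brute_force_decode(S, seq).pairs == frozenset({(0, 9)})

    def test_gradient_decoder_near_optimal(self, rng):
        """Decoded score within 95% of the enumerated optimum, mostly exact."""
        exact = 0
        for k in range(40):
            n = int(rng.integers(8, 15))
            seq = random_sequence(rng, n, f"o{k}")
            A = rng.uniform(-1, 1, size=(n, n))
            S = 0.5 * (A + A.T)
            dec = cf.constrained_decode(S, seq, _decode_cfg())
            opt = cf.brute_force_decode(S, seq)
            ds = matching_score(S, dec)
            os_ = matching_score(S, opt)
            assert ds >= 0.95 * os_ - 1e-12
            exact += np.isclose(ds, os_)
        assert exact >= 0.8 * 40
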