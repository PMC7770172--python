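"""Encoder-decoder contracts: shapes, symmetry, determinism, normalization."""

import numpy as np
import pytest

import crossfold as cf
from crossfold.autodiff import Tensor
from crossfold.network import ModelConfig, ScoreModel, attention, _layer_norm
from conftest import random_sequence


class TestAttention:
    def test_single_position_is_identity(self):
        out, w = attention([[1.0]], [[1.0]], [[1.0]])
        assert np.allclose(out, [[1.0]]) and np.allclose(w, [[1.0]])

    def test_constant_values_dominate(self, rng):
        v = np.tile(rng.normal(size=(1, 4)), (6, 1))
        out, _ = attention(rng.normal(size=(6, 4)), rng.normal(size=(6, 4)), v)
        assert np.allclose(out, v)

    def test_zero_keys_average_values(self, rng):
        v = rng.normal(size=(5, 3))
        out, w = attention(rng.normal(size=(5, 3)), np.zeros((5, 3)), v)
        assert np.allclose(out, np.tile(v.mean(axis=0), (5, 1)))
        assert np.allclose(w, 1 / 5)

    @pytest.mark.parametrize("mode", ["sqrt_d", "d"])
    def test_rows_stochastic(self, rng, mode):
        _, w = attention(rng.normal(size=(8, 4)), rng.normal(size=(8, 4)),
                         rng.normal(size=(8, 4)), scale_mode=mode)
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-6)


class TestModelConfig:
    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError):
            ModelConfig(d=10, n_heads=4)

    def test_round_trip_dict(self):
        cfg = ModelConfig(d=16, n_blocks=2, n_heads=2, conv_channels=(8, 4, 1))
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg


class TestForward:
    def test_scores_symmetric_any_length(self, tiny_model, rng):
        for n in (5, 12, 33):
            sm = tiny_model.model_forward(random_sequence(rng, n))
            assert sm.values.shape == (n, n)
            assert np.allclose(sm.values, sm.values.T, atol=1e-6)

    def test_determinism_same_seed(self, rng):
        seq = random_sequence(rng, 15)
        cfg = dict(d=8, n_blocks=1, n_heads=2, conv_channels=(4, 3, 1), seed=7)
        a = ScoreModel(ModelConfig(**cfg)).model_forward(seq)
        b = ScoreModel(ModelConfig(**cfg)).model_forward(seq)
        assert np.array_equal(a.values, b.values)

    def test_max_len_enforced(self, rng):
        model = ScoreModel(ModelConfig(d=8, n_blocks=1, n_heads=2,
                                       conv_channels=(4, 3, 1), max_len=30))
        with pytest.raises(ValueError, match="max_len"):
            model.model_forward(random_sequence(rng, 31))

    def test_padding_does_not_change_scores(self, tiny_model, rng):
        """A sequence scored alone equals its block in a padded batch."""
        seq = random_sequence(rng, 14)
        longer = random_sequence(rng, 25)
        alone = tiny_model.model_forward(seq).values
        batch, mask, _ = tiny_model.forward_batch(
            [cf.one_hot(seq), cf.one_hot(longer)])
        assert np.allclose(batch.data[0][:14, :14], alone, atol=1e-8)
        assert mask[0, :14, :14].all() and not mask[0, 14:].any()


class TestLayerNorm:
    def test_unit_statistics_before_affine(self, rng):
        x = Tensor(rng.normal(2.0, 3.0, size=(4, 6, 8)))
        y = _layer_norm(x, Tensor(np.ones(8)), Tensor(np.zeros(8)))
        assert np.allclose(y.data.mean(axis=-1), 0, atol=1e-8)
        assert np.allclose(y.data.var(axis=-1), 1, atol=1e-3)


class TestPairwiseAssemble:
    def test_features_symmetric_and_order_invariant(self, rng):
        h = Tensor(rng.normal(size=(1, 6, 8)))
        p = Tensor(rng.normal(size=(1, 6, 8)))
        f = ScoreModel.pairwise_assemble(h, p)
        assert f.shape == (1, 6, 6, 16)
        assert np.allclose(f.data, np.swapaxes(f.data, 1, 2))
        z = (h.data + p.data)[0]
        assert np.allclose(f.data[0, 2, 2, :8], z[2])  # diagonal self-combination

    def test_off_diagonal_is_mean_of_endpoints(self, rng):
        h = Tensor(rng.normal(size=(1, 2, 4)))
        f = ScoreModel.pairwise_assemble(h, Tensor(np.zeros((1, 2, 4))))
        expect = 0.5 * (h.data[0, 0] + h.data[0, 1])
        assert np.allclose(f.data[0, 0, 1, :4], expect)
        assert np.allclose(f.data[0, 1, 0, :4], expect)


class TestDecoder:
    def test_zero_weights_give_zero_scores(self, rng):
        model = ScoreModel(ModelConfig(d=8, n_blocks=1, n_heads=2, conv_channels=(4, 3, 1)))
        for s in range(3):
            model.params[f"conv{s}_W"].data[:] = 0
            model.params[f"conv{s}_b"].data[:] = 0
        feats = Tensor(rng.normal(size=(1, 7, 7, 16)))
        out = model.decoder_forward(feats, np.ones((1, 7, 7, 1)))
        assert np.allclose(out.data, 0)

    def test_output_symmetric_for_any_features(self, tiny_model, rng):
        feats = Tensor(rng.normal(size=(1, 9, 9, 16)))
        out = tiny_model.decoder_forward(feats, np.ones((1, 9, 9, 1)))
        assert np.allclose(out.data[0], out.data[0].T, atol=1e-6)

    def test_axis_permutation_of_symmetric_input_is_noop(self, tiny_model, rng):
        f = rng.normal(size=(1, 8, 8, 16))
        f = 0.5 * (f + np.swapaxes(f, 1, 2))
        a = tiny_model.decoder_forward(Tensor(f), np.ones((1, 8, 8, 1)))
        b = tiny_model.decoder_forward(Tensor(np.swapaxes(f, 1, 2)), np.ones((1, 8, 8, 1)))
        assert np.allclose(a.data, b.data)


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, rng):
        model = ScoreModel(ModelConfig(d=8, n_blocks=1, n_heads=2,
                                       conv_channels=(4, 3, 1), seed=5))
        seq = random_sequence(rng, 12)
        before = model.model_forward(seq).values
        path = tmp_path / "ckpt.npz"
        model.save(path)
        loaded = ScoreModel.load(path)
        assert loaded.cfg == model.cfg
        assert np.array_equal(loaded.model_forward(seq).values, before)
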