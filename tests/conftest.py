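import numpy as np
import pytest

import crossfold as cf


@pytest.fixture(scope="session")
def small_dataset():
    """30 synthetic (sequence, structure) pairs, lengths 20-40, some pseudoknotted."""
    return cf.make_dataset(cf.SynthConfig(n_items=30, length_range=(20, 40), pk_prob=0.2, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_model():
    cfg = cf.ModelConfig(d=8, n_blocks=1, n_heads=2, conv_channels=(4, 3, 1), seed=3)
    return cf.ScoreModel(cfg)


def random_sequence(rng: np.random.Generator, n: int, id: str = "rand") -> cf.RnaSequence:
    return cf.parse_sequence("".join(rng.choice(list("AUCG"), n)), id)
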