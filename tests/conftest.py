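import numpy as np
import pytest

from ecmil import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Small separable cohort shared by training-dependent tests."""
    cfg = synth.SynthConfig(
        n_nsmp=40, n_p53abn=30, planted_fraction=0.1, embed_dim=8,
        class_separation=3.0, signal_fraction=0.5, bag_size_range=(10, 20),
        seed=7,
    )
    return synth.gen_cohort(cfg)
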