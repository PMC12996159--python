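import numpy as np
import pytest

from migraphdec.network import MIGraphNet, ModelConfig
from migraphdec.synthetic import ClassRecipe, SynthSpec, generate

TINY = dict(C=4, T=64, n_bands=2, m=8, w=16, n_classes=2, n_heads=2, l=3)


@pytest.fixture
def tiny_config():
    return ModelConfig(**TINY)


@pytest.fixture
def tiny_model(tiny_config):
    """Deterministic small model in float64 for numerical comparisons."""
    return MIGraphNet(tiny_config, seed=1, dtype=np.float64)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_trialset():
    """6-channel 2-class set with mu-band ERD contrast; quick to filter."""
    spec = SynthSpec(
        classes=[
            ClassRecipe("a", (8, 12), [0, 1], erd_factor=0.25),
            ClassRecipe("b", (8, 12), [3, 4], erd_factor=0.25),
        ],
        n_trials_per_class=8,
        C=6,
        T=256,
        fs=250.0,
        snr_db=8.0,
        seed=7,
    )
    return generate(spec)
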