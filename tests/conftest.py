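import numpy as np
import pytest

from carlsim import BiasSpec, ExperimentConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unbiased():
    return BiasSpec(scheme="explicit", alpha_plus=0.1, alpha_minus=0.1)


def small_config(**overrides):
    """A fast default config for plumbing tests."""
    defaults = dict(
        task="rich",
        n=2,
        trials=50,
        bias=BiasSpec(scheme="fixed_sum", b=3.0),
        beta=4.0,
        n_sims=20,
        seed=7,
        record=("payoffs", "choices", "q_values"),
    )
    defaults.update(overrides)
    return ExperimentConfig(**defaults)


@pytest.fixture
def tiny_config():
    return small_config()
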