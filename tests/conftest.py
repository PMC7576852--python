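import numpy as np
import pytest

from liftucm.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """Fast study conditions for unit tests: short phases, few reps."""
    return SynthConfig(
        n_reps=6,
        lift_duration=0.6,
        lower_duration=0.6,
        pause_duration=0.25,
        lift_height=0.3,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """One participant at the full study conditions."""
    return generate_dataset(SynthConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
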