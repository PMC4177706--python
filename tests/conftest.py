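import numpy as np
import pytest

from olsim.model_core import Unit, UnitConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return UnitConfig()


@pytest.fixture
def small_unit_factory():
    """Build a small unit from a seed plus config overrides."""

    def factory(seed=0, **overrides):
        config = UnitConfig(**{"n_staff": 10, "n_educators": 2, "n_managers": 1,
                               "seed": seed, **overrides})
        return Unit(config, np.random.default_rng(seed))

    return factory
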