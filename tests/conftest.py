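import numpy as np
import pytest

import respmark as rm
from respmark.anfis import TrainConfig


@pytest.fixture(scope="session")
def short_sessions():
    """Five compact breathing sessions (20 s at 20 Hz), one per study cycle."""
    return rm.simulate_study(n_sessions=5, seed=11, duration_s=20.0, dt_s=0.05)


@pytest.fixture(scope="session")
def fast_train_config():
    return TrainConfig(n_rules=3, epochs=8, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
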