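import numpy as np
import pandas as pd
import pytest

from moraldm import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-participant null-coupling cohort shared across pipeline tests."""
    cfg = SimConfig(n_participants=60, seed=101)
    return cfg, simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
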