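import warnings

import numpy as np
import pytest

from sleepbeat.simulate import SimConfig, simulate_cohort, simulate_feature_cohort

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_stream_cohort():
    """Two participants, two nights, full streams — shared across tests."""
    return simulate_cohort(SimConfig(n_participants=2, n_days=2, seed=42))


@pytest.fixture(scope="session")
def feature_cohort():
    """Default-condition feature-level cohort (60 participants x 14 days)."""
    return simulate_feature_cohort(SimConfig(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
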