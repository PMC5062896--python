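import numpy as np
import pytest

from hemaclone import HealthyParams, PatientConfig


@pytest.fixture
def healthy():
    return HealthyParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_config():
    """Patient config tuned for quick deterministic tests (no trajectories)."""
    return PatientConfig(record_trajectory=False, keep_event_log=False)
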