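import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from prosocial_effort.epochs import EpochSet, default_time_axis
from prosocial_effort.synthetic_data import GenerativeConfig

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture
def times():
    return default_time_axis()


@pytest.fixture
def make_epochs(times):
    """Factory for small EpochSet objects on the standard 512 Hz grid."""

    def _make(data, channels=("FC3", "FCz", "FC4", "P3", "Pz", "P4")):
        data = np.asarray(data, dtype=float)
        table = pd.DataFrame({"trial": np.arange(data.shape[2])})
        return EpochSet(
            data=data, channel_labels=list(channels), trial_table=table
        )

    return _make


@pytest.fixture
def small_config():
    """A scaled-down generator for fast structural tests."""
    return GenerativeConfig(n_participants=4, seed=123)
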