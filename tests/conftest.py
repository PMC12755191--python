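import numpy as np
import pytest
from hypothesis import settings

from pulsediv import TemperatureProfile, build_design, run_design

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_profile():
    """A fast profile for unit tests: 150 steps, pulse at 100 for 20."""
    return TemperatureProfile(t_total=150, t_onset=100, pulse_len=20)


@pytest.fixture(scope="session")
def reduced_grid_records():
    """The reduced factorial used for simulation-level statistics:
    3 interaction-strength levels x 5 optimum means x 5 optimum ranges x
    5 replicates = 375 communities at the full 750-step protocol."""
    design = build_design(
        {
            "alpha_sd": [0.0, 0.25, 0.5],
            "bopt_mean": [15.0, 16.625, 18.25, 19.875, 21.5],
            "bopt_range": [0.0, 1.75, 3.5, 5.25, 7.0],
            "replicates": 5,
            "base_seed": 1,
        }
    )
    records = run_design(design)
    assert len(records) == design.size
    return records
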