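import numpy as np
import pytest

from sagepop.core_types_io import load_packaged_vital_rates
from sagepop.synthetic_data import (
    SimulationTruth,
    simulate_broods,
    simulate_females,
    simulate_nests,
    stage_rng,
)


@pytest.fixture(scope="session")
def packaged_rates():
    """The packaged 2013-2018 vital-rate table."""
    return load_packaged_vital_rates()


@pytest.fixture(scope="session")
def truth():
    """Simulation truth mirroring the packaged table's rates and cohorts."""
    return SimulationTruth.from_table(seed=42)


@pytest.fixture(scope="session")
def sim_cohorts(truth):
    """One simulated study: (females, nests, broods) at the default sizes."""
    females = simulate_females(truth, stage_rng(42, "females"))
    nests = simulate_nests(truth, stage_rng(42, "nests"))
    broods = simulate_broods(truth, stage_rng(42, "broods"))
    return females, nests, broods


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
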