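"""Shared fixtures: one synthetic session reused across the suite.

The 60-trial set (20 per class, ERD depth 0.5) is generated once per test
session; EMD feature extraction is the expensive stage, so its AF
matrices are cached at session scope as well.
"""

import numpy as np
import pytest

from afcsp.pipeline import trialset_to_afms
from afcsp.synth import SimConfig, generate_trialset

SESSION_SEED = 42


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def trialset(sim_config):
    return generate_trialset(sim_config)


@pytest.fixture(scope="session")
def afms(trialset):
    return trialset_to_afms(trialset)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
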