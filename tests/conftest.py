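import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from contextrl import ModelParams, default_config
from contextrl.synthetic_data import simulate_agent


@pytest.fixture(scope="session")
def cfg_partial():
    return default_config("partial")


@pytest.fixture(scope="session")
def cfg_complete():
    return default_config("complete")


@pytest.fixture(scope="session")
def ol1_params():
    # typical fitted values for the opposing-learning model, partial feedback
    return ModelParams(beta=0.02, alpha1=0.26, alpha2=0.26)


@pytest.fixture(scope="session")
def ol1_dataset(cfg_partial, ol1_params):
    ds = simulate_agent("OL1", ol1_params, cfg_partial, seed=7)
    assert not ds.excluded
    return ds


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
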