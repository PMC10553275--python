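import numpy as np
import pytest

from ecoflow import Params, init_world

# Base parameter point used throughout: moderate basal inflow (lam/eta = 1.5),
# division threshold well above the metabolic rate, weak mutation.
BASE = dict(lam=0.6, eta=0.4, d=2.0, c=0.1)


@pytest.fixture
def base_params():
    return Params(r=3.0, L=30, steps=300, burn_in=100, seed=7, **BASE)


@pytest.fixture
def small_world(base_params):
    return init_world(base_params)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
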