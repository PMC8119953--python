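import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cdomkit import CampaignConfig, make_component_library, simulate_campaign

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

# compact grids for unit tests: full spectral structure, ~7x fewer cells
SMALL_EX = np.arange(240.0, 461.0, 10.0)
SMALL_EM = np.arange(300.0, 561.0, 5.0)


@pytest.fixture(scope="session")
def small_grids():
    return SMALL_EX, SMALL_EM


@pytest.fixture(scope="session")
def small_library(small_grids):
    ex, em = small_grids
    return make_component_library(ex, em)


def _tiny_config(**overrides):
    base = dict(
        n_stations=4,
        salinities=(0.1, 5.8, 13.9, 31.2),
        treatments=("PB",),
        timepoints_days={"PB": (0, 3, 24)},
        replicates={"PB": 1},
        seed=99,
        ex_grid=SMALL_EX,
        em_grid=SMALL_EM,
    )
    base.update(overrides)
    return CampaignConfig(**base)


@pytest.fixture(scope="session")
def tiny_campaign():
    """12 samples on the compact grids, default (0.5%) noise."""
    return simulate_campaign(_tiny_config())


@pytest.fixture(scope="session")
def noiseless_campaign():
    """12 samples, zero noise: the tensor is exactly trilinear."""
    return simulate_campaign(
        _tiny_config(noise_multiplicative=0.0, noise_additive=0.0))


@pytest.fixture()
def tiny_config_factory():
    return _tiny_config
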