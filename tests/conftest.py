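import numpy as np
import pytest

import symmotif as sm


@pytest.fixture
def toy_matrix():
    """2-wide matrix: col1 (A:0, C:1, G:2, T:3), col2 (T:0, A:0.2, C:0.4, G:0.6)."""
    return sm.EnergyMatrix(
        "toy2", np.array([[0.0, 1.0, 2.0, 3.0], [0.2, 0.4, 0.6, 0.0]])
    )


@pytest.fixture(scope="session")
def models():
    return sm.default_models()


@pytest.fixture(scope="session")
def m7a1_sample(models):
    land = sm.enumerate_landscape(models["M7A-1"])
    return sm.sample_sites(land, sm.SampleConfig(n_sites=500, seed=11))


@pytest.fixture(scope="session")
def m7s1_sample(models):
    land = sm.enumerate_landscape(models["M7S-1"])
    return sm.sample_sites(land, sm.SampleConfig(n_sites=500, seed=11))


@pytest.fixture(scope="session")
def m6s1_sample(models):
    land = sm.enumerate_landscape(models["M6S-1"])
    return sm.sample_sites(land, sm.SampleConfig(n_sites=500, seed=11))
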