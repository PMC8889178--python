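import numpy as np
import pandas as pd
import pytest

from enmrange import geodata, synth
from enmrange.geodata import EnvStack, ExtentConfig


@pytest.fixture(scope="session")
def small_world() -> EnvStack:
    return synth.generate_world(synth.WorldSpec(shape=(40, 40)), seed=11)


@pytest.fixture(scope="session")
def flat_world() -> EnvStack:
    """Single-landmass world (no sea channel) for geometry tests."""
    return synth.generate_world(
        synth.WorldSpec(shape=(30, 30), two_islands=False), seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_stack(nrows=10, ncols=10, n_layers=2, mask=None, seed=0,
               lat_min=-49.0, lon_min=165.0, res=0.1, cartesian=True):
    """Small ad-hoc EnvStack with continuous layers for unit tests."""
    rng = np.random.default_rng(seed)
    layers = {f"v{i}": rng.normal(size=(nrows, ncols)) for i in range(n_layers)}
    extent = ExtentConfig(lat_min=lat_min, lat_max=lat_min + nrows * res,
                          lon_min=lon_min, lon_max=lon_min + ncols * res)
    return EnvStack(layers=layers, kinds={k: "continuous" for k in layers},
                    extent=extent, resolution=res, mask=mask, cartesian=cartesian)


@pytest.fixture
def stack10() -> EnvStack:
    return make_stack()
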