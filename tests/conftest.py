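import numpy as np
import pandas as pd
import pytest

from microconnectome.atlas import (AtlasSpec, build_synthetic_atlas,
                                   synth_neurons_and_segments)


@pytest.fixture(scope="session")
def small_atlas():
    """2 regions/hemisphere x 6 layers, square 6x6-pixel region patches."""
    spec = AtlasSpec(n_regions=2, n_layers=6, shape=(12, 12, 12),
                     voxel_size=100.0)
    return build_synthetic_atlas(spec, seed=0)


@pytest.fixture(scope="session")
def four_region_atlas():
    """4 regions/hemisphere x 6 layers on a 12x24 footprint."""
    spec = AtlasSpec(n_regions=4, n_layers=6, shape=(12, 24, 12),
                     voxel_size=100.0, n_modules=2)
    return build_synthetic_atlas(spec, seed=0)


@pytest.fixture(scope="session")
def neuron_tables(small_atlas):
    atlas, flatmap = small_atlas
    return synth_neurons_and_segments(atlas, flatmap, neuron_density=3e-6,
                                      seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
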