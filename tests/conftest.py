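import numpy as np
import pytest

from stainshift.model import DiscriminatorConfig, GeneratorConfig, build_models
from stainshift.synthetic_data import SyntheticDatasetSpec, make_dataset
from stainshift.training import tiles_to_model_arrays


@pytest.fixture(scope="session")
def tiny_bundle():
    """Four tiny networks on 32px tiles (fast unit-test scale)."""
    return build_models(GeneratorConfig.tiny(32), DiscriminatorConfig.tiny(32), seed=11)


@pytest.fixture(scope="session")
def tiny_batches():
    """Model-range 32px tile arrays for both domains plus their stats."""
    ds = make_dataset(SyntheticDatasetSpec(n_tiles_per_domain=6, tile_size=32, seed=5))
    arr_a, arr_b, stats = tiles_to_model_arrays(ds.tiles_a, ds.tiles_b)
    return arr_a, arr_b, stats


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
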