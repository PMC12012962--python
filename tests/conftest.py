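import numpy as np
import pytest

from solugraph.curation import CuratedDataset
from solugraph.gcn import GCNConfig
from solugraph.synthetic import SyntheticSpec, make_synthetic_dataset


@pytest.fixture(scope="session")
def tiny_dataset() -> CuratedDataset:
    """40 synthetic chemicals; enough to split and train a toy model."""
    return make_synthetic_dataset(SyntheticSpec(n=40, rng_seed=11))


@pytest.fixture(scope="session")
def small_dataset() -> CuratedDataset:
    """120 synthetic chemicals for mid-weight pipeline tests."""
    return make_synthetic_dataset(SyntheticSpec(n=120, rng_seed=7))


@pytest.fixture(scope="session")
def tiny_gcn_config() -> GCNConfig:
    """A down-scaled network for fast unit tests (architecture unchanged)."""
    return GCNConfig(layer_widths=(8, 12), dense_width=10, epochs=3, rng_seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
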