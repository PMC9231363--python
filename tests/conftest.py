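import numpy as np
import pytest

from bsblsel import (BlockStructure, EpochDataset, RegionMap,
                     builtin_region_map, standard_montage)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_structure():
    """Three blocks of four coordinates."""
    return BlockStructure.uniform(3, 4)


@pytest.fixture
def toy_dataset(rng, toy_structure):
    """Small well-conditioned regression instance over three blocks."""
    n, d = 20, toy_structure.n_features
    X = rng.standard_normal((n, d))
    w = np.zeros(d)
    w[toy_structure.block_slice(0)] = rng.standard_normal(4)
    y = X @ w + 0.1 * rng.standard_normal(n)
    ds = EpochDataset.__new__(EpochDataset)
    ds.features = X
    ds.labels = y
    ds.structure = toy_structure
    ds.channel_names = ["a", "b", "c"]
    ds.sampling_rate = None
    ds.codes = ds.trial = ds.epoch = None
    ds.true_chars = None
    ds.meta = {}
    return ds


@pytest.fixture(scope="session")
def montage59():
    return standard_montage(59)


@pytest.fixture(scope="session")
def regions59(montage59):
    return builtin_region_map(montage59)


@pytest.fixture
def toy_regions():
    return RegionMap.single(3)
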