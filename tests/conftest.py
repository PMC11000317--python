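import logging

import numpy as np
import pytest
from hypothesis import settings

from mbsig import MultiBlockDataset, SimulationSpec, generate_dataset
from mbsig.preprocess import total_intensity_normalize

logging.getLogger("mbsig").setLevel(logging.WARNING)

# reproducible property tests, no on-disk example database
settings.register_profile("repro", database=None, derandomize=True,
                          deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_dataset():
    """The study-shaped synthetic dataset: 12+8 samples, 102 NMR buckets,
    290 lipids, planted 9-metabolite signature, seed 1."""
    dataset, truth = generate_dataset(SimulationSpec(seed=1))
    return dataset, truth


@pytest.fixture(scope="session")
def normalized_dataset(default_dataset):
    dataset, truth = default_dataset
    blocks = [total_intensity_normalize(dataset.block("nmr")),
              dataset.block("lipid")]
    return MultiBlockDataset(dataset.samples, blocks), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_two_class(rng):
    """A linearly separable toy problem: two distant clusters, n=10, p=6."""
    n_half = 5
    X = np.vstack([
        rng.normal(0.0, 0.3, size=(n_half, 6)),
        rng.normal(4.0, 0.3, size=(n_half, 6)),
    ])
    y = np.array([0] * n_half + [1] * n_half)
    return X, y
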