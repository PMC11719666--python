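"""Shared fixtures.

The default synthetic dataset (30 seeds per class, master seed 42) and
its feature tables are expensive to build, so they are computed once per
session and shared by the fusion, chemometrics, classification and
acceptance tests.
"""

import numpy as np
import pytest

from seedvision import feature_table, generate_dataset, reduce_dataset


@pytest.fixture(scope="session")
def default_dataset():
    images, manifest = generate_dataset(30, seed=42)
    return images, manifest


@pytest.fixture(scope="session")
def raw_table(default_dataset):
    images, _ = default_dataset
    return feature_table(images)


@pytest.fixture(scope="session")
def fireice_table(default_dataset):
    images, _ = default_dataset
    return reduce_dataset(images)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
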