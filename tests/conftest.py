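"""Shared fixtures: all data generated programmatically at test time."""

import numpy as np
import pytest

from glycocode.catalog import make_glyco_catalog
from glycocode.io import ExpressionMatrix
from glycocode.simulate import (
    BulkSimConfig,
    SCSimConfig,
    simulate_bulk,
    simulate_single_cell,
)


@pytest.fixture(scope="session")
def catalog():
    return make_glyco_catalog()


@pytest.fixture(scope="session")
def bulk_default():
    """Default four-cohort synthetic bulk design, fixed seed."""
    config = BulkSimConfig(seed=11)
    return config, simulate_bulk(config)


@pytest.fixture(scope="session")
def discovery_tumours(bulk_default):
    """Tumour samples of the first cohort plus their metadata."""
    config, cohorts = bulk_default
    matrix, metadata = cohorts[0]
    tumours = [m for m in metadata if m.condition == "tumour"]
    return matrix.subset_samples([m.sample_id for m in tumours]), tumours, config


@pytest.fixture(scope="session")
def sc_default():
    """Default synthetic single-cell dataset, fixed seed."""
    return simulate_single_cell(SCSimConfig(seed=11))


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(5)
    return ExpressionMatrix(
        [f"g{i}" for i in range(10)],
        [f"s{j}" for j in range(6)],
        rng.normal(size=(10, 6)),
    )
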