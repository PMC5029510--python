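import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from syntroscan import (
    build_matrix,
    default_config,
    example_catalog,
    simulate_cohort,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def catalog():
    return example_catalog("COG")


@pytest.fixture(scope="session")
def default_cohort(catalog):
    """One default synthetic cohort (fixed seed) with its truth."""
    config = default_config(catalog, seed=12345)
    tables, metadata, truth = simulate_cohort(config, catalog)
    return tables, metadata, truth


@pytest.fixture(scope="session")
def default_matrix(catalog, default_cohort):
    tables, metadata, _ = default_cohort
    return build_matrix(tables, catalog, metadata)


@pytest.fixture()
def rng():
    return np.random.default_rng(202401)
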