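import numpy as np
import pytest

from lacscore import PhantomConfig, generate_atlas, generate_cohort


def small_config(**overrides) -> PhantomConfig:
    """Reduced-grid phantom config used throughout the suite for speed."""
    defaults = dict(grid_shape=(32, 32, 32), seed=42)
    defaults.update(overrides)
    return PhantomConfig(**defaults)


@pytest.fixture
def config():
    return small_config()


@pytest.fixture(scope="session")
def session_config():
    return small_config()


@pytest.fixture(scope="session")
def atlas(session_config):
    return generate_atlas(session_config, seed=7)


@pytest.fixture(scope="session")
def cohort_dataset(session_config):
    """One fully generated 11-subject cohort, shared across tests."""
    return generate_cohort(session_config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
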