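import numpy as np
import pytest

from cremsex import (
    load_reference_registry,
    load_trait_registry,
    simulate_observer_pairs,
    simulate_study_series,
)


@pytest.fixture(scope="session")
def registry():
    return load_trait_registry()


@pytest.fixture(scope="session")
def present_standard():
    return load_reference_registry("present-study")


@pytest.fixture(scope="session")
def study_table():
    """Synthetic analogue of the reference collection (124 adults, 50 M / 74 F)."""
    return simulate_study_series(seed=20260923)


@pytest.fixture(scope="session")
def observer_table(study_table):
    """Dual-observer replicates over the study table with 0.2 mm noise."""
    return simulate_observer_pairs(study_table, error_sd=0.2, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
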