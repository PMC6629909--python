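import numpy as np
import pytest

from dfcstates import (
    PlantedStateSpec,
    RunConfig,
    extract_samples,
    simulate_bold,
)


@pytest.fixture(scope="session")
def small_spec():
    """A reduced planted cohort: 3 states, 12 regions, 6 subjects,
    400 timepoints (20 windows of 20), kept small so unit tests stay
    fast while every pipeline stage still has real work to do."""
    return PlantedStateSpec(
        n_states=3,
        n_regions=12,
        n_subjects=6,
        n_timepoints=400,
        window_length=20,
        n_modules=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    series, truth = simulate_bold(small_spec)
    return series, truth


@pytest.fixture(scope="session")
def small_collection(small_spec, small_cohort):
    series, _ = small_cohort
    return extract_samples(series, small_spec.window_length)


@pytest.fixture(scope="session")
def small_config():
    return RunConfig(window_length=20, group_size=5, random_seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(2718)
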