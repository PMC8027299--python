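import numpy as np
import pytest

from cancerburden import synthetic as syn


@pytest.fixture(scope="session")
def small_config() -> syn.SimulationConfig:
    """A 5-province, 6-age-group, 10-year world small enough for fast tests."""
    return syn.SimulationConfig(
        n_provinces=5,
        n_age_groups=6,
        year_start=2000,
        year_end=2009,
        population_base=400_000.0,
    )


@pytest.fixture(scope="session")
def adjacency(small_config) -> np.ndarray:
    return syn.make_geography(small_config.n_provinces, seed=11)


@pytest.fixture(scope="session")
def truth(small_config, adjacency) -> syn.TruthSurface:
    return syn.simulate_truth(small_config, adjacency, seed=12)


@pytest.fixture(scope="session")
def population(small_config) -> syn.PopulationTable:
    return syn.make_population(small_config, seed=13)


@pytest.fixture(scope="session")
def covariates(small_config) -> syn.CovariateTable:
    return syn.make_covariates(small_config, seed=14)


@pytest.fixture(scope="session")
def life_table(small_config) -> syn.LifeTable:
    return syn.make_life_table(small_config)


@pytest.fixture(scope="session")
def clean_registries(truth, population) -> syn.SimulatedRegistries:
    """Fully observed registries: no under-registration, missingness or dups."""
    obs = syn.ObservationConfig(
        pi_crs=1.0,
        pi_drs=1.0,
        pi_ssocr=1.0,
        missing_age=0.0,
        missing_sex=0.0,
        missing_province=0.0,
        duplicate_prob=0.0,
    )
    return syn.simulate_registry(truth, population, obs, seed=15)


@pytest.fixture(scope="session")
def noisy_registries(truth, population) -> syn.SimulatedRegistries:
    obs = syn.ObservationConfig(
        pi_crs=0.8,
        pi_drs=0.9,
        pi_ssocr=0.6,
        missing_age=0.08,
        missing_sex=0.05,
        missing_province=0.06,
        duplicate_prob=0.1,
    )
    return syn.simulate_registry(truth, population, obs, seed=16)
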