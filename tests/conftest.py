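import dataclasses

import pytest

import airhappy as ah
from airhappy.inference import McmcConfig, run_mcmc
from airhappy.model import Dataset


@pytest.fixture(scope="session")
def tiny_scenario():
    """A scaled-down scenario: 8 cities of 30-60 respondents (~360 total)."""
    return dataclasses.replace(ah.default_scenario(), n_cities=8,
                               city_size_range=(30, 60), seed=42)


@pytest.fixture(scope="session")
def tiny_survey(tiny_scenario):
    return ah.simulate_survey(tiny_scenario)


@pytest.fixture(scope="session")
def model1_spec():
    return ah.default_ladder()["model1"]


@pytest.fixture(scope="session")
def tiny_dataset(tiny_survey, model1_spec):
    individuals, cities = tiny_survey
    return Dataset.from_frames(individuals, cities, model1_spec)


@pytest.fixture(scope="session")
def small_fit(tiny_dataset):
    """A short two-chain fit shared across structural tests."""
    config = McmcConfig(n_chains=2, n_iterations=1200, burn_in=600, thin=2, seed=7)
    return run_mcmc(tiny_dataset, config=config)
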