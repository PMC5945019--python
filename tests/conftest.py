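import logging
from types import SimpleNamespace

import numpy as np
import pytest

from sfcmpipe.config import PipelineConfig
from sfcmpipe.pipeline import cleaned_samples, run_cleaning, run_grouping
from sfcmpipe.synthetic import (
    FieldScenario,
    default_archetypes,
    generate_field_series,
    generate_training,
)

logging.getLogger("sfcmpipe").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def archetypes():
    return {a.name: a for a in default_archetypes()}


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced field campaign used by unit/integration tests."""
    return FieldScenario(n_samples=12, particles_per_sample=2000, seed=7)


@pytest.fixture(scope="session")
def small_field(small_scenario):
    return generate_field_series(small_scenario)


@pytest.fixture(scope="session")
def lab_training():
    """Default lab-culture training set (pulse -> featurize path)."""
    return generate_training(seed=2)


@pytest.fixture(scope="session")
def small_cfg():
    return PipelineConfig(
        subset_size=20_000,
        trees_importance=501,
        trees_classify=301,
        trees_biovolume=501,
        random_seed=7,
    )


@pytest.fixture(scope="session")
def small_run(small_field, lab_training, small_cfg):
    """Cleaning + grouping on the reduced campaign, shared across tests."""
    samples, truth = small_field
    cleaning = run_cleaning(samples, lab_training.live_other(), small_cfg)
    cleaned = cleaned_samples(samples, cleaning.result)
    grouping = run_grouping(cleaned, lab_training.groups(), small_cfg)
    return SimpleNamespace(
        samples=samples,
        truth=truth,
        cleaning=cleaning,
        cleaned=cleaned,
        grouping=grouping,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
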