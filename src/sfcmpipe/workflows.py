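"""Reference end-to-end study on the default synthetic conditions.

Runs the complete method — generate the default field series and lab
training set, cleaning pass, grouping pass, biovolume forest, held-out
per-species prediction, and community aggregation — and collects the
headline quantities (classifier out-of-bag errors, cluster count,
biovolume R², held-out species mean, end-to-end recovery correlation).
Both the test suite and ``scripts/acceptance.py`` drive this function so
the numbers they report come from one code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .forests import LabeledTraining, fit_biovolume_regressor
from .pipeline import CleaningOutput, GroupingOutput, cleaned_samples, run_cleaning, run_grouping
from .preprocess import TraitMatrix, log_transform_eligible
from .quantify import estimate_communities, validate_loglog
from .synthetic import (
    FieldScenario,
    default_archetypes,
    generate_field_series,
    generate_pulses_with_truth,
    generate_training,
)
from .pulses import featurize

logger = logging.getLogger("sfcmpipe")


@dataclass
class StudyResult:
    """Everything the reference study computes."""

    scenario: FieldScenario
    samples: list
    truth: pd.DataFrame
    cleaning: CleaningOutput
    grouping: GroupingOutput
    biovolume_model: object
    estimates: list
    cleaning_oob_error: float       # fraction
    grouping_oob_error: float       # fraction
    n_raw_clusters: int
    biovolume_oob_r2: float
    heldout_species: str
    heldout_mean_biovolume: float   # µm³
    density_recovery_r: float       # log10 total density, estimate vs truth

    def summary(self) -> dict:
        return {
            "cleaning_oob_error_pct": 100.0 * self.cleaning_oob_error,
            "grouping_oob_error_pct": 100.0 * self.grouping_oob_error,
            "n_raw_clusters": self.n_raw_clusters,
            "biovolume_oob_r2": self.biovolume_oob_r2,
            "heldout_mean_biovolume_um3": self.heldout_mean_biovolume,
            "density_recovery_r": self.density_recovery_r,
        }


def heldout_species_mean(model, archetype, n: int, seed) -> float:
    """Mean predicted biovolume over freshly generated archetype particles."""
    particles, _ = generate_pulses_with_truth(archetype, n, seed)
    frame = pd.DataFrame([featurize(p).traits for p in particles])
    frame.index = pd.Index([p.particle_id for p in particles], name="particle_id")
    return float(model.predict(TraitMatrix(frame)).mean())


def run_default_study(seed: int = 1, scenario: FieldScenario | None = None,
                      cfg: PipelineConfig | None = None,
                      heldout_n: int = 200) -> StudyResult:
    """Run the whole pipeline on the default synthetic study conditions.

    ``seed`` drives every random element (field series, lab training,
    subsetting, clustering, forests, held-out draws) through fixed
    offsets, so one integer reproduces the entire study.
    """
    scenario = scenario or FieldScenario(seed=seed)
    cfg = cfg or PipelineConfig(random_seed=seed)

    samples, truth = generate_field_series(scenario)
    train = generate_training(seed=seed + 101)

    cleaning = run_cleaning(samples, train.live_other(), cfg)
    cl_samples = cleaned_samples(samples, cleaning.result)
    grouping = run_grouping(cl_samples, train.groups(), cfg)

    bio_train = train.biovolume()
    bio_train = LabeledTraining(log_transform_eligible(bio_train.matrix), bio_train.labels)
    bio_model = fit_biovolume_regressor(bio_train, cfg.trees_biovolume, seed + 202)

    archetypes = {a.name: a for a in default_archetypes()}
    heldout = "Synechococcus"
    heldout_mean = heldout_species_mean(
        bio_model, archetypes[heldout], heldout_n, seed + 303
    )

    estimates = estimate_communities(samples, cleaning.result, grouping, bio_model)
    total_truth = truth[truth["group"] == "total"].set_index("sample_id")
    est = pd.Series({e.sample_id: e.total_density for e in estimates})
    r = validate_loglog(
        total_truth.loc[est.index, "true_density_per_ml"], est
    ).r

    result = StudyResult(
        scenario=scenario,
        samples=samples,
        truth=truth,
        cleaning=cleaning,
        grouping=grouping,
        biovolume_model=bio_model,
        estimates=estimates,
        cleaning_oob_error=cleaning.forest.oob_error,
        grouping_oob_error=grouping.forest.oob_error,
        n_raw_clusters=cleaning.clusters.n_clusters,
        biovolume_oob_r2=bio_model.oob_r2,
        heldout_species=heldout,
        heldout_mean_biovolume=heldout_mean,
        density_recovery_r=r,
    )
    logger.info("default study summary: %s", result.summary())
    return result
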