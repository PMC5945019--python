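"""Generator structure: determinism, composition, pigment logic, separability."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from sfcmpipe.clustering import flowpeaks_cluster
from sfcmpipe.config import ClusterParams
from sfcmpipe.preprocess import TraitMatrix, log_transform_eligible
from sfcmpipe.pulses import featurize
from sfcmpipe.synthetic import (
    FieldScenario,
    archetype_base_traits,
    default_archetypes,
    generate_field_series,
    generate_pulses,
    generate_training,
    sample_noise_traits,
    sample_traits,
)


class TestArchetypes:
    def test_table_of_ten_species(self, archetypes):
        assert len(archetypes) == 10
        assert archetypes["Synechococcus"].mean_biovolume == 13.4
        assert archetypes["Anabaena"].mean_biovolume == 15478.7

    def test_cyano_ratio_below_all_eukaryotes(self, archetypes):
        ratios = {
            name: archetype_base_traits(a)["Red1Red2.ratio"]
            for name, a in archetypes.items()
        }
        cyano = [r for n, r in ratios.items()
                 if archetypes[n].group == "cyanobacteria"]
        eukaryote = [r for n, r in ratios.items()
                     if archetypes[n].group != "cyanobacteria"]
        assert max(cyano) < min(eukaryote)

    def test_asterionella_colony_peaks(self, archetypes):
        counts = [
            featurize(p).traits["FL.Red.Number.of.cells"]
            for p in generate_pulses(archetypes["Asterionella"], 30, 0)
        ]
        values, freq = np.unique(counts, return_counts=True)
        assert values[np.argmax(freq)] == 6

    def test_synechococcus_shorter_than_anabaena(self, archetypes):
        short = [featurize(p).traits["FWS.Length"]
                 for p in generate_pulses(archetypes["Synechococcus"], 40, 1)]
        long = [featurize(p).traits["FWS.Length"]
                for p in generate_pulses(archetypes["Anabaena"], 40, 1)]
        paired = np.array(short) < np.array(long)
        assert paired.mean() >= 0.95

    def test_pulse_determinism(self, archetypes):
        a = generate_pulses(archetypes["Chlorella"], 5, 42)
        b = generate_pulses(archetypes["Chlorella"], 5, 42)
        for pa, pb in zip(a, b):
            for channel in pa.pulses:
                np.testing.assert_array_equal(pa[channel].values, pb[channel].values)

    def test_trait_sampler_tracks_pulse_path(self, archetypes, rng):
        """Key trait medians agree between the fast sampler and the
        featurized-pulse path (within ~20%)."""
        arch = archetypes["Synura"]
        fast, _ = sample_traits(arch, 300, rng)
        slow = pd.DataFrame(
            [featurize(p).traits for p in generate_pulses(arch, 120, 3)]
        )
        for trait in ("FL.Red.Maximum", "FWS.Range", "Red1Red2.ratio",
                      "X2.FL.Red.Gradient", "FL.Red.Fill.factor"):
            ratio = fast[trait].median() / slow[trait].median()
            assert 0.8 < ratio < 1.25, trait


class TestTraining:
    def test_default_composition(self, lab_training):
        labels = lab_training.labels
        assert (labels["label"] == "live").sum() == 1200
        assert (labels["label"] == "other").sum() == 8400
        per_species = labels[labels["label"] == "live"]["species"].value_counts()
        assert (per_species == 120).all()

    def test_biovolume_targets_within_panel_range(self, lab_training):
        bio = lab_training.labels["biovolume_um3"].dropna()
        assert bio.min() >= 13.4 * 0.5
        assert bio.max() <= 15478.7 * 2.0

    def test_trait_count(self, lab_training):
        assert lab_training.matrix.data.shape[1] >= 67

    def test_training_determinism(self):
        a = generate_training(n_live=60, n_other=140, seed=9, mode="traits")
        b = generate_training(n_live=60, n_other=140, seed=9, mode="traits")
        pd.testing.assert_frame_equal(a.matrix.data, b.matrix.data)


class TestFieldSeries:
    def test_pooled_live_fraction(self, small_field):
        samples, truth = small_field
        totals = truth[truth["group"] == "total"]
        particle_density = samples[0].particle_concentration_per_ul * 1000.0
        pooled = totals["true_density_per_ml"].sum() / (len(samples) * particle_density)
        assert 0.03 <= pooled <= 0.07

    def test_truth_conservation(self, small_field):
        """Group truth densities + noise = particle concentration x 1000."""
        samples, truth = small_field
        conc = samples[0].particle_concentration_per_ul * 1000.0
        by_sample = truth.groupby("sample_id")
        for sid, chunk in by_sample:
            chunk = chunk.set_index("group")
            groups = [g for g in chunk.index if g not in ("total", "noise")]
            total = chunk.loc[groups, "true_density_per_ml"].sum()
            assert total == pytest.approx(chunk.loc["total", "true_density_per_ml"])
            assert total + chunk.loc["noise", "true_density_per_ml"] == pytest.approx(conc)

    def test_no_microscopy_error_limit(self):
        scenario = FieldScenario(
            n_samples=4, particles_per_sample=1000, microscopy_error_cv=0.0,
            detection_limit_cells_per_ml=0.0, seed=11,
        )
        _, truth = generate_field_series(scenario)
        rows = truth[truth["group"] != "noise"]
        np.testing.assert_allclose(
            rows["microscopy_density_per_ml"], rows["true_density_per_ml"]
        )

    def test_detection_limit_produces_zero_counts(self, small_field):
        """The declining cyanobacteria dip below the microscopy detection
        limit in at least one sample, recorded as a zero count."""
        _, truth = small_field
        cyano = truth[truth["group"] == "cyanobacteria"]
        below = cyano[(cyano["true_density_per_ml"] > 0)
                      & (cyano["microscopy_density_per_ml"] == 0.0)]
        assert len(below) >= 1

    def test_field_determinism(self):
        scenario = FieldScenario(n_samples=3, particles_per_sample=500, seed=21)
        a_samples, a_truth = generate_field_series(scenario)
        b_samples, b_truth = generate_field_series(scenario)
        pd.testing.assert_frame_equal(a_truth, b_truth)
        for sa, sb in zip(a_samples, b_samples):
            pd.testing.assert_frame_equal(sa.traits, sb.traits)


TOP_TRAITS = [
    "FL.Red.Maximum", "FL.Red.Gradient", "FL.Orange.Maximum", "FL.Orange.Gradient",
    "FL.Yellow.Maximum", "FWS.Maximum", "FWS.Range", "X2.FL.Red.Maximum",
    "X2.FL.Red.Range", "Red1Red2.ratio",
]


def mixture_ari(cv: float, seed: int = 0) -> float:
    """ARI between generator truth and recovered clusters at a given
    within-species coefficient of variation."""
    rng = np.random.default_rng(seed)
    archetypes = {a.name: a for a in default_archetypes()}
    composition = {
        "Synura": 950, "Chroomonas": 360, "Chlorella": 400,
        "Synechococcus": 140, "Cryptomonas": 70, "Microcystis": 45,
        "Ankistrodesmus": 75,
    }
    frames, origin = [], []
    for name, count in composition.items():
        frame, _ = sample_traits(archetypes[name], count, rng, cv=cv)
        frames.append(frame)
        origin += [name] * count
    noise = sample_noise_traits(12_000, rng)
    frames.append(noise)
    origin += ["noise"] * len(noise)
    matrix = log_transform_eligible(TraitMatrix(pd.concat(frames, ignore_index=True)))
    model = flowpeaks_cluster(matrix.restrict(TOP_TRAITS), ClusterParams(seed=seed))
    return adjusted_rand_score(np.array(origin), model.labels)


def test_separability_dial():
    """At the default cv the clustering recovers generator truth almost
    perfectly; raising the within-species spread degrades it monotonically."""
    scores = [mixture_ari(cv) for cv in (0.15, 0.4, 0.8)]
    assert scores[0] >= 0.95
    assert scores[0] >= scores[1] >= scores[2]
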