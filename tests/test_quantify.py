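"""Density/biovolume aggregation identities and log-log validation."""

import numpy as np
import pandas as pd
import pytest

from sfcmpipe.errors import DomainError, IntegrityError
from sfcmpipe.forests import LabeledTraining, fit_biovolume_regressor
from sfcmpipe.io import Sample
from sfcmpipe.preprocess import TraitMatrix
from sfcmpipe.quantify import (
    CommunityEstimate,
    community_density,
    group_density,
    predict_biovolumes,
    total_and_group_biovolume,
    validate_loglog,
)


def make_sample(n=10, conc=1.0):
    traits = pd.DataFrame(
        {"A": np.linspace(1, 2, n)},
        index=pd.Index([f"p{i}" for i in range(n)], name="particle_id"),
    )
    return Sample("s1", traits, particle_concentration_per_ul=conc,
                  check_concentration=False)


class TestCommunityDensity:
    def test_arithmetic(self):
        assert community_density(make_sample(), 0.05) == pytest.approx(50.0)

    def test_zero_live_fraction(self):
        assert community_density(make_sample(), 0.0) == 0.0

    def test_zero_particles_warns(self, caplog):
        sample = Sample("s0", pd.DataFrame({"A": []}),
                        particle_concentration_per_ul=1.0, check_concentration=False)
        assert community_density(sample, 0.5) == 0.0

    def test_bad_fraction_rejected(self):
        with pytest.raises(DomainError):
            community_density(make_sample(), 1.5)


class TestGroupDensity:
    def test_proportional_split(self):
        out = group_density(100.0, {"a": 0.5, "b": 0.3})
        assert out == {"a": 50.0, "b": 30.0}

    def test_empty_fractions(self):
        assert group_density(100.0, {}) == {}

    def test_conservation_at_unit_sum(self):
        out = group_density(80.0, {"a": 0.25, "b": 0.75})
        assert sum(out.values()) == pytest.approx(80.0)

    def test_oversum_rejected(self):
        with pytest.raises(IntegrityError):
            group_density(10.0, {"a": 0.7, "b": 0.5})


class TestBiovolumeAggregation:
    def test_simple_product(self):
        bio = pd.Series([100.0] * 5)
        labels = pd.Series(["g"] * 5)
        est = total_and_group_biovolume("s1", 50.0, {"g": 50.0}, bio, labels)
        assert est.total_biovolume == pytest.approx(5000.0)
        assert est.group_biovolume["g"] == pytest.approx(5000.0)

    def test_single_group_equals_total(self):
        bio = pd.Series([10.0, 30.0, 20.0])
        labels = pd.Series(["g"] * 3)
        est = total_and_group_biovolume("s1", 60.0, {"g": 60.0}, bio, labels)
        assert est.group_biovolume["g"] == pytest.approx(est.total_biovolume)

    def test_conservation_with_unassigned(self):
        """Assigned plus unassigned contributions reconstruct the total."""
        rng = np.random.default_rng(0)
        bio = pd.Series(rng.uniform(10, 1000, 200))
        labels = pd.Series(["a"] * 80 + ["b"] * 70 + ["unassigned"] * 50)
        total = 500.0
        fractions = {g: (labels == g).mean() for g in ("a", "b")}
        est = total_and_group_biovolume(
            "s1", total, {g: total * f for g, f in fractions.items()}, bio, labels
        )
        unassigned_density = total * (labels == "unassigned").mean()
        unassigned_bio = unassigned_density * bio[labels == "unassigned"].mean()
        reconstructed = sum(est.group_biovolume.values()) + unassigned_bio
        assert reconstructed == pytest.approx(est.total_biovolume, rel=1e-9)

    def test_density_without_particles_rejected(self):
        bio = pd.Series([10.0])
        labels = pd.Series(["a"])
        with pytest.raises(IntegrityError):
            total_and_group_biovolume("s1", 10.0, {"ghost": 5.0}, bio, labels)


class TestPredictBiovolumes:
    def test_constant_model_constant_predictions(self, rng):
        data = pd.DataFrame(rng.normal(size=(30, 2)), columns=["A", "B"])
        train = LabeledTraining(TraitMatrix(data), pd.Series([28.7] * 30))
        model = fit_biovolume_regressor(train, 101, seed=0)
        sample = Sample("s1", data.iloc[:5], check_concentration=False)
        pred = predict_biovolumes(model, [sample])["s1"]
        np.testing.assert_allclose(pred, 28.7, rtol=1e-6)
        assert (pred > 0).all()

    def test_missing_trait_named(self, rng):
        data = pd.DataFrame(rng.normal(size=(30, 2)), columns=["A", "B"])
        train = LabeledTraining(TraitMatrix(data), pd.Series([10.0] * 15 + [90.0] * 15))
        model = fit_biovolume_regressor(train, 101, seed=0)
        sample = Sample("s1", data[["A"]], check_concentration=False)
        with pytest.raises(DomainError, match="B"):
            predict_biovolumes(model, [sample])


class TestCommunityEstimateInvariants:
    def test_group_density_cannot_exceed_total(self):
        with pytest.raises(IntegrityError):
            CommunityEstimate("s1", total_density=10.0, group_density={"a": 20.0})

    def test_biovolume_consistency_enforced(self):
        with pytest.raises(IntegrityError):
            CommunityEstimate("s1", total_density=10.0, total_biovolume=1.0,
                              mean_cell_biovolume=5.0)


class TestValidateLogLog:
    def test_identity(self, rng):
        x = rng.uniform(10, 1000, 40)
        result = validate_loglog(x, x)
        assert result.r == pytest.approx(1.0)
        assert result.slope == pytest.approx(1.0)
        assert result.intercept == pytest.approx(0.0, abs=1e-12)

    def test_scale_shift(self, rng):
        x = rng.uniform(10, 1000, 40)
        result = validate_loglog(x, 100.0 * x)
        assert result.slope == pytest.approx(1.0)
        assert result.intercept == pytest.approx(2.0)

    def test_scaling_y_changes_only_intercept(self, rng):
        x = rng.uniform(10, 1000, 50)
        y = x * rng.lognormal(0, 0.2, 50)
        base = validate_loglog(x, y)
        scaled = validate_loglog(x, 7.0 * y)
        assert scaled.slope == pytest.approx(base.slope, rel=1e-9)
        assert scaled.r == pytest.approx(base.r, rel=1e-9)
        assert scaled.intercept == pytest.approx(base.intercept + np.log10(7.0), rel=1e-9)

    def test_detection_limit_substitution(self, rng):
        x = np.array([0.0, 100.0, 200.0, 400.0, 800.0])
        y = np.array([14.0, 100.0, 200.0, 400.0, 800.0])
        result = validate_loglog(x, y, detection_limit=28.0)
        # zero replaced by 14 = 0.5 x 28 -> perfect identity
        assert result.r == pytest.approx(1.0)
        assert result.slope == pytest.approx(1.0)

    def test_zero_without_limit_rejected(self):
        with pytest.raises(DomainError):
            validate_loglog([0.0, 1.0, 2.0], [1.0, 1.0, 2.0])

    def test_leverage_exclusion_drops_outlier(self, rng):
        x = np.concatenate([rng.uniform(90, 110, 30), [1e6]])
        y = x * rng.lognormal(0, 0.05, 31)
        result = validate_loglog(x, y, leverage_exclusion=True)
        assert 30 in result.excluded_point_ids
        assert result.n == 30

    def test_too_few_points_rejected(self):
        with pytest.raises(DomainError):
            validate_loglog([1.0, 2.0], [1.0, 2.0])
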