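"""Cell-density and biovolume estimation plus validation statistics.

Community cell density is the instrument particle concentration times
the live-cell proportion found by the cleaning pass; group densities
multiply that by each group's share of the live cells; biovolumes
multiply densities by mean per-cell biovolume predicted by the trained
forest.  Validation regresses log10 SFCM estimates on log10 reference
(microscopy) estimates and reports the Pearson correlation, slope and
intercept with 95% confidence intervals, with optional substitution of
below-detection-limit zeros and optional exclusion of high-leverage
points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DomainError, IntegrityError
from .forests import ForestModel
from .preprocess import TraitMatrix

logger = logging.getLogger("sfcmpipe")


@dataclass
class CommunityEstimate:
    """Per-sample community and per-group densities and biovolumes."""

    sample_id: str
    total_density: float                  # cells/mL
    group_density: dict = field(default_factory=dict)    # group -> cells/mL
    total_biovolume: float = 0.0          # µm³/mL
    group_biovolume: dict = field(default_factory=dict)  # group -> µm³/mL
    mean_cell_biovolume: float = 0.0      # µm³
    live_fraction: float = 0.0

    def __post_init__(self) -> None:
        values = [self.total_density, self.total_biovolume, *self.group_density.values(),
                  *self.group_biovolume.values()]
        if any(v < 0 for v in values):
            raise IntegrityError(f"{self.sample_id}: negative density/biovolume")
        assigned = sum(self.group_density.values())
        if assigned > self.total_density * (1 + 1e-9) + 1e-12:
            raise IntegrityError(
                f"{self.sample_id}: group densities exceed total "
                f"({assigned:.6g} > {self.total_density:.6g})"
            )
        expected = self.total_density * self.mean_cell_biovolume
        if expected > 0 and abs(self.total_biovolume - expected) > 1e-9 * expected:
            raise IntegrityError(
                f"{self.sample_id}: total_biovolume inconsistent with "
                "density x mean cell biovolume"
            )


def predict_biovolumes(model: ForestModel, samples) -> dict:
    """Per-particle biovolume predictions (µm³) for each cleaned sample.

    Returns ``{sample_id: Series}`` indexed by particle id; predictions
    are strictly positive by construction (forest mean on the log10
    scale, back-transformed).
    """
    if model.kind != "regressor":
        raise DomainError("predict_biovolumes needs a regressor ForestModel")
    out = {}
    for sample in samples:
        if sample.n_particles == 0:
            out[sample.sample_id] = pd.Series(dtype=float)
            continue
        pred = model.predict(TraitMatrix(sample.traits))
        out[sample.sample_id] = pd.Series(pred, index=sample.traits.index)
    return out


def community_density(sample, live_fraction: float) -> float:
    """Whole-community cell density: concentration x 1000 x live fraction."""
    if not (0.0 <= live_fraction <= 1.0):
        raise DomainError("live_fraction must lie in [0, 1]")
    conc = sample.particle_concentration_per_ul
    if conc is None:
        if not sample.volume_analyzed_ul:
            raise DomainError(f"{sample.sample_id}: no concentration or volume")
        conc = sample.n_particles / sample.volume_analyzed_ul
    if sample.n_particles == 0:
        logger.warning("%s: zero particles measured, density 0", sample.sample_id)
        return 0.0
    return float(conc) * 1000.0 * live_fraction


def group_density(total: float, fractions: dict) -> dict:
    """Per-group density = total x fraction of live cells in the group."""
    if any(not (0.0 <= f <= 1.0) for f in fractions.values()):
        raise DomainError("group fractions must lie in [0, 1]")
    if sum(fractions.values()) > 1.0 + 1e-9:
        raise IntegrityError("group fractions sum above 1")
    return {g: total * f for g, f in fractions.items()}


def total_and_group_biovolume(
    sample_id: str,
    total_density: float,
    densities: dict,
    biovolumes: pd.Series,
    group_labels: pd.Series,
    live_fraction: float = 0.0,
) -> CommunityEstimate:
    """Assemble a :class:`CommunityEstimate` from densities and predictions.

    ``biovolumes`` holds per-particle predictions for the retained
    particles of one sample; ``group_labels`` aligns a group name with
    each of them.  Total biovolume = total density x mean biovolume of
    all retained cells; each group's biovolume uses the mean over that
    group's cells only, so assigned-group biovolumes plus the
    unassigned contribution reconstruct the total exactly.
    """
    if len(biovolumes) != len(group_labels):
        raise DomainError("biovolumes/group_labels length mismatch")
    mean_bio = float(biovolumes.mean()) if len(biovolumes) else 0.0
    group_bio = {}
    for group, density in densities.items():
        members = biovolumes[np.asarray(group_labels) == group]
        if len(members) == 0:
            if density > 0:
                raise IntegrityError(
                    f"{sample_id}: group {group!r} has density {density} "
                    "but no member particles"
                )
            group_bio[group] = 0.0
        else:
            group_bio[group] = density * float(members.mean())
    return CommunityEstimate(
        sample_id=sample_id,
        total_density=total_density,
        group_density=dict(densities),
        total_biovolume=total_density * mean_bio,
        group_biovolume=group_bio,
        mean_cell_biovolume=mean_bio,
        live_fraction=live_fraction,
    )


def estimate_communities(samples, cleaning, grouping, biovolume_model) -> list:
    """End-to-end per-sample estimates from pipeline outputs.

    ``samples`` are the original field samples, ``cleaning`` a
    :class:`~sfcmpipe.pipeline.CleaningResult`, ``grouping`` a
    :class:`~sfcmpipe.pipeline.GroupingOutput` (or ``None`` to skip
    groups) and ``biovolume_model`` the trained regressor.
    """
    from .pipeline import UNASSIGNED, cleaned_samples

    samples = list(samples)
    cleaned = cleaned_samples(samples, cleaning)
    predictions = predict_biovolumes(biovolume_model, cleaned)
    estimates = []
    for sample, clean in zip(samples, cleaned):
        sid = sample.sample_id
        lf = cleaning.live_fraction[sid]
        total = community_density(sample, lf)
        bio = predictions[sid]
        if grouping is not None:
            labels = pd.Series(grouping.group_labels[sid], index=clean.traits.index)
            n = len(labels)
            fractions = {
                g: float((labels == g).sum()) / n
                for g in sorted(labels.unique())
                if g != UNASSIGNED and n > 0
            }
        else:
            labels = pd.Series(["live"] * len(bio), index=bio.index)
            fractions = {}
        densities = group_density(total, fractions)
        estimates.append(
            total_and_group_biovolume(sid, total, densities, bio, labels, lf)
        )
    return estimates


@dataclass
class ValidationResult:
    """Log-log agreement statistics between paired estimate series."""

    r: float
    slope: float
    intercept: float
    slope_ci: tuple
    intercept_ci: tuple
    n: int
    excluded_point_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise DomainError("correlation outside [-1, 1]")
        if not (self.slope_ci[0] <= self.slope <= self.slope_ci[1]):
            raise DomainError("slope outside its confidence interval")

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_ci": list(self.slope_ci),
            "intercept_ci": list(self.intercept_ci),
            "n": self.n,
            "excluded_point_ids": list(self.excluded_point_ids),
        }


def validate_loglog(
    x,
    y,
    detection_limit: float | None = None,
    substitution_factor: float = 0.5,
    leverage_exclusion: bool = False,
    ids=None,
) -> ValidationResult:
    """Regress log10(y) on log10(x) and report agreement statistics.

    ``x`` is the reference (e.g. microscopy) series and ``y`` the SFCM
    estimate.  Zeros in ``x`` are permitted when ``detection_limit`` is
    given: they are replaced by ``substitution_factor x detection_limit``
    (the standard below-detection convention).  With
    ``leverage_exclusion``, points whose hat-matrix leverage exceeds 3x
    the average (3 x 2/n) are dropped and reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ids = np.asarray(ids) if ids is not None else np.arange(len(x))
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be equal-length 1-d arrays")
    if np.any(y <= 0):
        raise DomainError("y must be strictly positive")
    if np.any(x <= 0):
        if detection_limit is None:
            raise DomainError("x contains non-positive values and no detection limit")
        x = np.where(x <= 0, substitution_factor * detection_limit, x)

    lx, ly = np.log10(x), np.log10(y)
    excluded: list = []
    if leverage_exclusion:
        design = sm.add_constant(lx)
        leverage = sm.OLS(ly, design).fit().get_influence().hat_matrix_diag
        cut = 3.0 * 2.0 / len(lx)
        drop = leverage > cut
        excluded = [i for i, d in zip(ids, drop) if d]
        if drop.any():
            logger.info("validate_loglog: excluding %d high-leverage points", drop.sum())
            lx, ly = lx[~drop], ly[~drop]
    if len(lx) < 3:
        raise DomainError("fewer than 3 points after exclusion")

    fit = sm.OLS(ly, sm.add_constant(lx)).fit()
    ci = fit.conf_int(alpha=0.05)
    r = float(stats.pearsonr(lx, ly).statistic)
    return ValidationResult(
        r=r,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        n=int(len(lx)),
        excluded_point_ids=excluded,
    )
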