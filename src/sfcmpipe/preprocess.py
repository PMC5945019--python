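"""Trait-table transformations preceding selection and clustering.

Three steps, applied in this order: log10-transform of every trait whose
minimum is strictly positive (cytometry traits are heavily right-skewed),
greedy pruning of trait pairs with |Pearson r| above a threshold, and
pooled equal-per-sample subsetting so one clustering run represents the
whole measurement series without being dominated by any single sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError

logger = logging.getLogger("sfcmpipe")


@dataclass
class TraitMatrix:
    """A rectangular particle x trait table with transform provenance.

    ``data`` is indexed by particle identity; ``sample_ids`` (optional)
    aligns a sample identity with every row; ``transform_log`` lists the
    traits currently stored as log10 values.
    """

    data: pd.DataFrame
    sample_ids: pd.Series | None = None
    transform_log: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.data.columns.has_duplicates:
            raise DomainError("duplicate trait names in matrix")
        if self.data.isna().any().any():
            raise DomainError("trait matrix contains missing values")
        if self.sample_ids is not None and len(self.sample_ids) != len(self.data):
            raise DomainError("sample_ids length mismatch")
        self.transform_log = set(self.transform_log)

    @property
    def traits(self) -> list:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)

    def restrict(self, traits) -> "TraitMatrix":
        """Column-subset view preserving provenance."""
        traits = list(traits)
        missing = [t for t in traits if t not in self.data.columns]
        if missing:
            raise DomainError(f"traits not in matrix: {missing}")
        return TraitMatrix(
            self.data[traits].copy(),
            None if self.sample_ids is None else self.sample_ids.copy(),
            self.transform_log & set(traits),
        )


def log_transform_eligible(m: TraitMatrix) -> TraitMatrix:
    """log10-transform every trait whose minimum value is > 0.

    Traits containing zeros or negatives are left untouched, as are
    traits already flagged in ``transform_log`` (the flagging is
    idempotent).  The flag set makes the transform exactly invertible.
    """
    data = m.data.copy()
    flagged = set(m.transform_log)
    mins = data.min(axis=0)
    for trait in data.columns:
        if trait in flagged:
            continue
        if mins[trait] > 0:
            data[trait] = np.log10(data[trait])
            flagged.add(trait)
    logger.info(
        "log_transform_eligible: %d/%d traits on log10 scale",
        len(flagged),
        data.shape[1],
    )
    return TraitMatrix(data, m.sample_ids, flagged)


def invert_log_transform(m: TraitMatrix) -> TraitMatrix:
    """Undo :func:`log_transform_eligible` exactly (10**x on flagged traits)."""
    data = m.data.copy()
    for trait in m.transform_log:
        if trait in data.columns:
            data[trait] = 10.0 ** data[trait]
    return TraitMatrix(data, m.sample_ids, set())


def prune_correlated(m: TraitMatrix, threshold: float) -> tuple:
    """Drop the later member of every trait pair with |Pearson r| > threshold.

    Columns are scanned in input order; a column is removed as soon as it
    correlates beyond the threshold with any *retained* earlier column,
    which guarantees that no surviving pair exceeds the threshold.  The
    removal order is returned for the audit log.  Constant (zero
    variance) columns have their correlations defined as 0 and are kept,
    with a warning.
    """
    if not (0 < threshold < 1):
        raise ConfigurationError("correlation threshold must lie in (0, 1)")
    if len(m) < 2:
        raise DomainError("prune_correlated needs at least 2 rows")
    corr = m.data.corr().to_numpy()
    constant = m.data.std(axis=0).to_numpy() == 0
    if constant.any():
        logger.warning(
            "prune_correlated: constant columns retained: %s",
            [t for t, c in zip(m.traits, constant) if c],
        )
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)

    kept: list = []
    kept_idx: list = []
    removed: list = []
    for j, trait in enumerate(m.traits):
        if kept_idx and np.any(np.abs(corr[j, kept_idx]) > threshold):
            removed.append(trait)
        else:
            kept.append(trait)
            kept_idx.append(j)
    logger.info(
        "prune_correlated: kept %d traits, removed %d (|r| > %.2f)",
        len(kept),
        len(removed),
        threshold,
    )
    return m.restrict(kept), removed


def pooled_subset(samples, target_total: int, seed) -> TraitMatrix:
    """Draw an equal number of particles from every sample, pooled.

    floor(target_total / n_samples) particles are drawn uniformly
    without replacement from each sample (all of them, with a warning, if
    a sample is smaller); each row keeps its sample of origin so the
    subset's provenance is auditable.  Deterministic given ``seed``.
    """
    samples = list(samples)
    if not samples:
        raise DomainError("pooled_subset: no samples")
    if target_total < len(samples):
        raise ConfigurationError(
            f"target_total {target_total} < number of samples {len(samples)}"
        )
    per_sample = target_total // len(samples)
    rng = np.random.default_rng(seed)
    frames = []
    ids = []
    for sample in samples:
        n = sample.n_particles
        if n <= per_sample:
            if n < per_sample:
                logger.warning(
                    "pooled_subset: sample %s has only %d particles (< %d), using all",
                    sample.sample_id,
                    n,
                    per_sample,
                )
            chunk = sample.traits
        else:
            rows = rng.choice(n, size=per_sample, replace=False)
            rows.sort()
            chunk = sample.traits.iloc[rows]
        frames.append(chunk)
        ids.extend([sample.sample_id] * len(chunk))
    data = pd.concat(frames, axis=0)
    sample_ids = pd.Series(ids, index=data.index, name="sample_id")
    logger.info(
        "pooled_subset: %d rows pooled from %d samples (%d per sample)",
        len(data),
        len(samples),
        per_sample,
    )
    return TraitMatrix(data, sample_ids)
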