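"""Random-forest contracts: importance ranking, classification, biovolume regression.

Forests play three roles in the pipeline: (a) ranking trait importance on
labelled lab-culture data (Gini mean decrease in impurity), (b)
classifying every field particle into the clusters found on a pooled
subset, and (c) regressing single-cell biovolume on the full trait
vector.  scikit-learn provides the ensembles; this module pins down the
contracts — odd tree counts, out-of-bag statistics, trait-list checking,
deterministic tie-breaking — and the log10 target scale of the biovolume
regressor.

Biovolume spans three orders of magnitude across species, so the
regressor is fit on log10(biovolume) and its out-of-bag R² is defined on
that scale; a linear-scale fit would be dominated entirely by the
largest species.  Predictions are back-transformed to µm³.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .errors import DomainError
from .preprocess import TraitMatrix

logger = logging.getLogger("sfcmpipe")


@dataclass
class LabeledTraining:
    """A trait matrix plus per-row labels (categorical or continuous)."""

    matrix: TraitMatrix
    labels: pd.Series

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.matrix):
            raise DomainError("label count must equal row count")


@dataclass
class ImportanceRanking:
    """Traits ordered by descending Gini mean-decrease importance."""

    entries: list  # list of (trait_name, importance)

    def __post_init__(self) -> None:
        scores = [s for _, s in self.entries]
        if any(b > a for a, b in zip(scores, scores[1:])):
            raise DomainError("importance ranking must be descending")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def traits(self) -> list:
        return [t for t, _ in self.entries]

    def as_series(self) -> pd.Series:
        return pd.Series(dict(self.entries)).sort_values(ascending=False)


def select_top_k(ranking: ImportanceRanking, k: int) -> list:
    """First ``k`` trait names of a ranking."""
    if k > len(ranking):
        raise DomainError(f"k={k} exceeds ranking length {len(ranking)}")
    return ranking.traits[:k]


@dataclass
class ForestModel:
    """A fitted forest plus everything needed to apply it honestly.

    ``traits_used`` and ``transform_log`` travel with the estimator so
    prediction refuses tables missing a required trait and re-applies the
    training-time log10 transform.
    """

    kind: str  # "classifier" | "regressor"
    traits_used: list
    n_trees: int
    seed: int
    estimator: object
    transform_log: set = field(default_factory=set)
    oob_error: float | None = None
    oob_r2: float | None = None
    format_version: int = 1

    def _design(self, matrix: TraitMatrix) -> np.ndarray:
        missing = [t for t in self.traits_used if t not in matrix.data.columns]
        if missing:
            raise DomainError(f"prediction input lacks trait(s) {missing}")
        data = matrix.data[self.traits_used]
        to_log = [t for t in self.traits_used if t in self.transform_log and t not in matrix.transform_log]
        if to_log:
            data = data.copy()
            # Trees only use value order, so clipping at a tiny positive
            # floor is a safe way to log-transform occasional zeros.
            data[to_log] = np.log10(data[to_log].clip(lower=1e-12))
        return data.to_numpy(dtype=float)

    def predict(self, matrix: TraitMatrix) -> np.ndarray:
        X = self._design(matrix)
        if self.kind == "classifier":
            return self.estimator.predict(X)
        return 10.0 ** self.estimator.predict(X)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ForestModel":
        model = joblib.load(path)
        if not isinstance(model, ForestModel):
            raise DomainError(f"{path} does not hold a ForestModel")
        return model


def _check_classification_labels(labels: pd.Series, min_per_class: int = 1) -> None:
    counts = labels.value_counts()
    if len(counts) < 2:
        raise DomainError("classification requires at least 2 classes")
    if counts.min() < min_per_class:
        raise DomainError(
            f"every class needs >= {min_per_class} rows (got {counts.min()})"
        )


def rank_importance(train: LabeledTraining, n_trees: int, seed: int) -> ImportanceRanking:
    """Rank traits by Gini mean-decrease importance, descending.

    Ties are broken lexicographically by trait name so that rankings are
    reproducible bit-for-bit.
    """
    _check_classification_labels(train.labels, min_per_class=10)
    rf = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=-1
    )
    rf.fit(train.matrix.data.to_numpy(dtype=float), train.labels.to_numpy())
    table = pd.DataFrame(
        {"trait": train.matrix.traits, "importance": rf.feature_importances_}
    ).sort_values(["importance", "trait"], ascending=[False, True], kind="stable")
    return ImportanceRanking(list(table.itertuples(index=False, name=None)))


def fit_classifier(train: LabeledTraining, n_trees: int, seed: int) -> ForestModel:
    """Fit an odd-tree-count forest classifier with out-of-bag error."""
    _check_classification_labels(train.labels)
    rf = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, oob_score=True, n_jobs=-1
    )
    rf.fit(train.matrix.data.to_numpy(dtype=float), train.labels.to_numpy())
    oob_error = 1.0 - float(rf.oob_score_)
    logger.info("fit_classifier: %d trees, OOB error %.4f", n_trees, oob_error)
    return ForestModel(
        kind="classifier",
        traits_used=train.matrix.traits,
        n_trees=n_trees,
        seed=seed,
        estimator=rf,
        transform_log=set(train.matrix.transform_log),
        oob_error=oob_error,
    )


def fit_biovolume_regressor(train: LabeledTraining, n_trees: int, seed: int) -> ForestModel:
    """Fit the biovolume forest on log10 targets; predictions are in µm³.

    Requires strictly positive biovolume targets covering at least two
    distinct values (species).  The out-of-bag R² is computed on the
    log10 scale.
    """
    y = train.labels.to_numpy(dtype=float)
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        raise DomainError("biovolume targets must be finite and > 0")
    # With a constant target the out-of-bag R² is undefined; skip it.
    want_oob = len(np.unique(y)) > 1
    rf = RandomForestRegressor(
        n_estimators=n_trees, random_state=seed, oob_score=want_oob, n_jobs=-1
    )
    rf.fit(train.matrix.data.to_numpy(dtype=float), np.log10(y))
    oob_r2 = float(rf.oob_score_) if want_oob else 1.0
    logger.info("fit_biovolume_regressor: %d trees, OOB R2 (log10) %.4f", n_trees, oob_r2)
    return ForestModel(
        kind="regressor",
        traits_used=train.matrix.traits,
        n_trees=n_trees,
        seed=seed,
        estimator=rf,
        transform_log=set(train.matrix.transform_log),
        oob_r2=oob_r2,
    )
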