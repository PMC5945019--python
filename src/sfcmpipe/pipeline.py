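"""The two clustering passes: data cleaning and functional-group identification.

Pass A (cleaning) separates live phytoplankton cells from everything
else (bacteria, detritus, electronic noise): rank traits on labelled lab
data (live vs other), keep the top 10, pool an equal-per-sample subset
of the field series, density-peak cluster it, flag the high-chlorophyll
clusters as live, train a classifier on the cluster labels and apply it
to every particle of every sample, retaining only live-cluster members.

Pass B (grouping) repeats the procedure on the cleaned data with
group-labelled lab cells and the top 8 traits, then maps the abundant
clusters (>= ``min_group_fraction`` of the subset) onto functional
groups using pigment heuristics: the phycocyanin-rich cluster (lowest
Red1Red2.ratio) is cyanobacteria; the cluster with jointly lowest
X2.FL.Red.Gradient and FL.Red.First is cryptophytes; the highest
remaining Red1Red2.ratio with strong chlorophyll signal is green algae;
the most abundant remainder is chrysophytes.  Where the published
workflow relied on visual 3-D inspection, these rules are explicit,
logged and overridable through the configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import ClusterModel, ClusterSummary, cluster_summary, flowpeaks_cluster
from .config import ClusterParams, PipelineConfig
from .errors import DomainError, PipelineError
from .forests import (
    ForestModel,
    ImportanceRanking,
    LabeledTraining,
    fit_classifier,
    rank_importance,
    select_top_k,
)
from .io import Sample
from .preprocess import TraitMatrix, log_transform_eligible, pooled_subset, prune_correlated

logger = logging.getLogger("sfcmpipe")

ASSIGNABLE_GROUPS = ("cyanobacteria", "chrysophytes", "cryptophytes", "green_algae")
UNASSIGNED = "unassigned"


@dataclass
class CleaningResult:
    """Outcome of the cleaning pass."""

    live_clusters: set
    cluster_labels: dict      # sample_id -> per-particle cluster id (aligned with traits)
    retained: dict            # sample_id -> Index of retained particle ids
    live_fraction: dict       # sample_id -> retained / total

    def __post_init__(self) -> None:
        for sid, frac in self.live_fraction.items():
            if not (0.0 <= frac <= 1.0):
                raise DomainError(f"{sid}: live_fraction outside [0, 1]")


@dataclass
class CleaningOutput:
    result: CleaningResult
    forest: ForestModel
    clusters: ClusterModel
    ranking: ImportanceRanking
    selected_traits: list
    pruned_traits: list
    summary: ClusterSummary


@dataclass
class GroupAssignment:
    """Cluster -> functional-group mapping with per-cluster rationale."""

    mapping: dict  # cluster_id -> (group, rationale)

    def __post_init__(self) -> None:
        cyano = [c for c, (g, _) in self.mapping.items() if g == "cyanobacteria"]
        if len(cyano) > 1:
            raise DomainError("at most one cluster may be assigned to cyanobacteria")

    def group_of(self, cluster_id: int) -> str:
        entry = self.mapping.get(int(cluster_id))
        return entry[0] if entry else UNASSIGNED

    def as_series(self) -> pd.Series:
        return pd.Series({c: g for c, (g, _) in self.mapping.items()})


@dataclass
class GroupingOutput:
    group_labels: dict        # sample_id -> per-retained-particle group name
    cluster_labels: dict      # sample_id -> per-retained-particle cluster id
    assignment: GroupAssignment
    forest: ForestModel
    clusters: ClusterModel
    ranking: ImportanceRanking
    selected_traits: list
    pruned_traits: list
    summary: ClusterSummary


def _prepare_lab(train: LabeledTraining, cfg: PipelineConfig):
    """Transform + prune the lab matrix, preserving the labels."""
    lab = log_transform_eligible(train.matrix)
    lab, removed = prune_correlated(lab, cfg.correlation_threshold)
    return LabeledTraining(lab, train.labels), removed


def _median_log10(summary: ClusterSummary, trait: str) -> pd.Series:
    if trait not in summary.medians_raw.columns:
        raise DomainError(f"cluster summary lacks trait {trait!r}")
    return np.log10(summary.medians_raw[trait].clip(lower=1e-12))


def flag_live_clusters(model: ClusterModel, summary: ClusterSummary,
                       cfg: PipelineConfig) -> set:
    """Flag clusters as live phytoplankton by chlorophyll fluorescence.

    A cluster is live when its median log10 FL.Red.Range exceeds the
    dimmest cluster's by at least ``live_margin_log10``.  An explicit
    ``live_cluster_override`` list in the configuration replaces the
    rule entirely (the codified version of manual inspection).
    """
    if cfg.live_cluster_override is not None:
        flagged = set(int(c) for c in cfg.live_cluster_override)
        logger.info("flag_live_clusters: override in effect -> %s", sorted(flagged))
        return flagged
    logs = _median_log10(summary, "FL.Red.Range")
    base = logs.min()
    flagged = {int(c) for c, v in logs.items() if v - base >= cfg.live_margin_log10}
    logger.info(
        "flag_live_clusters: %d/%d clusters flagged (margin %.2f dex over %.2f)",
        len(flagged), len(logs), cfg.live_margin_log10, base,
    )
    return flagged


def _classify_samples(forest: ForestModel, samples) -> dict:
    labels = {}
    for sample in samples:
        matrix = TraitMatrix(sample.traits)
        labels[sample.sample_id] = forest.predict(matrix)
    return labels


def run_cleaning(samples, train: LabeledTraining, cfg: PipelineConfig | None = None
                 ) -> CleaningOutput:
    """Run the full data-cleaning pass over a field series.

    ``train`` is the lab-culture table with live/other labels on the raw
    (untransformed) trait scale.  Every particle in every sample ends up
    labelled with a cluster id; particles in live-flagged clusters are
    retained.
    """
    cfg = cfg or PipelineConfig()
    samples = list(samples)
    if not samples:
        raise DomainError("run_cleaning: no samples")
    seed = cfg.random_seed

    lab, pruned = _prepare_lab(train, cfg)
    ranking = rank_importance(lab, cfg.trees_importance, seed)
    top = select_top_k(ranking, cfg.n_top_clean)
    logger.info("cleaning: top-%d traits %s", cfg.n_top_clean, top)

    subset = pooled_subset(samples, cfg.subset_size, seed + 1)
    sub_sel = log_transform_eligible(subset.restrict(top))
    params = ClusterParams(
        tol=cfg.cluster_params.tol, h0=cfg.cluster_params.h0, h=cfg.cluster_params.h,
        k0=cfg.cluster_params.k0, max_climb_iters=cfg.cluster_params.max_climb_iters,
        seed=seed,
    )
    model = flowpeaks_cluster(sub_sel, params)
    summary = cluster_summary(model, log_transform_eligible(subset))
    live = flag_live_clusters(model, summary, cfg)
    if not live:
        raise PipelineError(
            "no cluster exceeds the live fluorescence margin; review "
            "live_margin_log10 or supply live_cluster_override"
        )

    forest = fit_classifier(
        LabeledTraining(sub_sel, pd.Series(model.labels, index=sub_sel.data.index)),
        cfg.trees_classify, seed,
    )
    cluster_labels = _classify_samples(forest, samples)

    retained = {}
    live_fraction = {}
    total_in = total_kept = 0
    for sample in samples:
        labels = cluster_labels[sample.sample_id]
        mask = np.isin(labels, sorted(live))
        retained[sample.sample_id] = sample.traits.index[mask]
        live_fraction[sample.sample_id] = (
            float(mask.mean()) if len(labels) else 0.0
        )
        total_in += len(labels)
        total_kept += int(mask.sum())
    logger.info(
        "cleaning: retained %d/%d particles (%.2f%%) across %d samples; "
        "classifier OOB error %.4f",
        total_kept, total_in, 100.0 * total_kept / max(total_in, 1),
        len(samples), forest.oob_error,
    )
    result = CleaningResult(
        live_clusters=live,
        cluster_labels=cluster_labels,
        retained=retained,
        live_fraction=live_fraction,
    )
    return CleaningOutput(result, forest, model, ranking, top, pruned, summary)


def cleaned_samples(samples, result: CleaningResult) -> list:
    """Per-sample views containing only the retained (live) particles."""
    out = []
    for sample in samples:
        keep = result.retained[sample.sample_id]
        out.append(
            Sample(
                sample_id=sample.sample_id,
                traits=sample.traits.loc[keep],
                depth_m=sample.depth_m,
                timestamp=sample.timestamp,
                volume_analyzed_ul=sample.volume_analyzed_ul,
                particle_concentration_per_ul=sample.particle_concentration_per_ul,
                check_concentration=False,
            )
        )
    return out


def assign_groups(summary: ClusterSummary, cfg: PipelineConfig | None = None
                  ) -> GroupAssignment:
    """Map abundant clusters to functional groups by pigment heuristics.

    Rules are evaluated in order on clusters holding at least
    ``min_group_fraction`` of the subset; each assignment records its
    rationale.  Ties go to the lower cluster id, with a warning.
    """
    cfg = cfg or PipelineConfig()
    for trait in ("Red1Red2.ratio", "X2.FL.Red.Gradient", "FL.Red.First", "FL.Red.Range"):
        if trait not in summary.medians_raw.columns:
            raise DomainError(f"assign_groups: summary lacks trait {trait!r}")
    med = summary.medians_raw
    fractions = summary.fractions

    mapping: dict = {}
    abundant = [int(c) for c in fractions.index if fractions[c] >= cfg.min_group_fraction]
    for c in fractions.index:
        if int(c) not in abundant:
            mapping[int(c)] = (
                UNASSIGNED,
                f"fraction {fractions[c]:.3f} below min_group_fraction "
                f"{cfg.min_group_fraction}",
            )
    remaining = sorted(abundant)

    def _warn_tie(values: pd.Series, winner: int, what: str) -> None:
        ties = [int(c) for c in values.index if values[c] == values[winner] and int(c) != winner]
        if ties:
            logger.warning("assign_groups: tie on %s between %s and %s; "
                           "lower cluster id wins", what, winner, ties)

    # Rule 1: lowest Red1Red2.ratio below the ceiling -> cyanobacteria
    if remaining:
        ratios = med.loc[remaining, "Red1Red2.ratio"]
        winner = int(ratios.sort_index().idxmin())
        _warn_tie(ratios, winner, "Red1Red2.ratio")
        if ratios[winner] <= cfg.cyano_ratio_max:
            mapping[winner] = (
                "cyanobacteria",
                f"lowest Red1Red2.ratio ({ratios[winner]:.3g} <= "
                f"{cfg.cyano_ratio_max}): phycocyanin-rich",
            )
            remaining.remove(winner)

    # Rule 2: jointly lowest X2.FL.Red.Gradient and FL.Red.First -> cryptophytes
    if len(remaining) >= 2:
        grad_rank = med.loc[remaining, "X2.FL.Red.Gradient"].rank(method="min")
        first_rank = med.loc[remaining, "FL.Red.First"].rank(method="min")
        joint = grad_rank + first_rank
        winner = int(joint.sort_index().idxmin())
        _warn_tie(joint, winner, "X2.FL.Red.Gradient + FL.Red.First rank")
        mapping[winner] = (
            "cryptophytes",
            "jointly lowest X2.FL.Red.Gradient and FL.Red.First with "
            f"intermediate Red1Red2.ratio ({med.loc[winner, 'Red1Red2.ratio']:.3g})",
        )
        remaining.remove(winner)

    # Rule 3: highest remaining Red1Red2.ratio with high FL.Red.Range -> green algae
    if len(remaining) >= 2:
        ratios = med.loc[remaining, "Red1Red2.ratio"]
        winner = int(ratios.sort_index().idxmax())
        _warn_tie(ratios, winner, "Red1Red2.ratio")
        mapping[winner] = (
            "green_algae",
            f"highest remaining Red1Red2.ratio ({ratios[winner]:.3g}) with "
            f"FL.Red.Range {med.loc[winner, 'FL.Red.Range']:.3g}",
        )
        remaining.remove(winner)

    # Rule 4: most abundant remaining -> chrysophytes
    if remaining:
        fr = fractions.loc[remaining]
        winner = int(fr.sort_index().idxmax())
        _warn_tie(fr, winner, "abundance")
        mapping[winner] = (
            "chrysophytes",
            f"most abundant remaining cluster (fraction {fr[winner]:.3f})",
        )
        remaining.remove(winner)
    for c in remaining:
        mapping[c] = (UNASSIGNED, "abundant but no assignment rule left")

    assignment = GroupAssignment(mapping)
    for cid in sorted(mapping):
        logger.info("assign_groups: cluster %d -> %s (%s)", cid, *mapping[cid])
    return assignment


def run_grouping(cleaned, train_live: LabeledTraining,
                 cfg: PipelineConfig | None = None) -> GroupingOutput:
    """Run the functional-group pass on cleaned (live-cell) samples."""
    cfg = cfg or PipelineConfig()
    cleaned = list(cleaned)
    if not cleaned:
        raise DomainError("run_grouping: no samples")
    seed = cfg.random_seed

    lab, pruned = _prepare_lab(train_live, cfg)
    ranking = rank_importance(lab, cfg.trees_importance, seed + 10)
    top = select_top_k(ranking, cfg.n_top_group)
    logger.info("grouping: top-%d traits %s", cfg.n_top_group, top)

    subset = pooled_subset(cleaned, cfg.subset_size, seed + 11)
    sub_sel = log_transform_eligible(subset.restrict(top))
    params = ClusterParams(
        tol=cfg.cluster_params.tol, h0=cfg.cluster_params.h0, h=cfg.cluster_params.h,
        k0=cfg.cluster_params.k0, max_climb_iters=cfg.cluster_params.max_climb_iters,
        seed=seed + 11,
    )
    model = flowpeaks_cluster(sub_sel, params)
    summary = cluster_summary(model, log_transform_eligible(subset))

    n_abundant = int((summary.fractions >= cfg.min_group_fraction).sum())
    if n_abundant < 2:
        logger.warning(
            "run_grouping: only %d abundant cluster(s); single-group output",
            n_abundant,
        )
    assignment = assign_groups(summary, cfg)

    forest = fit_classifier(
        LabeledTraining(sub_sel, pd.Series(model.labels, index=sub_sel.data.index)),
        cfg.trees_classify, seed + 12,
    )
    cluster_labels = _classify_samples(forest, cleaned)
    group_labels = {
        sid: np.array([assignment.group_of(c) for c in labels])
        for sid, labels in cluster_labels.items()
    }
    n_total = sum(len(v) for v in group_labels.values())
    n_assigned = sum(int((v != UNASSIGNED).sum()) for v in group_labels.values())
    logger.info(
        "grouping: %d/%d cleaned particles (%.1f%%) in assigned clusters; "
        "classifier OOB error %.4f",
        n_assigned, n_total, 100.0 * n_assigned / max(n_total, 1), forest.oob_error,
    )
    return GroupingOutput(
        group_labels, cluster_labels, assignment, forest, model,
        ranking, top, pruned, summary,
    )
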