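# Methods

This note documents the models, numerical choices and limitations behind
`sfcmpipe`, in the order data flow through the pipeline.

## Pulse features (`sfcmpipe.pulses`)

A scanning flow cytometer records one intensity series per optical
channel per particle (forward/sideward scatter; red fluorescence under
488 nm and 642 nm excitation; orange; yellow). Instrument vendors ship
their own scalar summaries of these pulses but do not publish the exact
formulas, so the descriptors here are explicit reconstructions, each a
small named function that users can replace with an instrument-exact
definition:

| descriptor | definition | unit |
|---|---|---|
| Maximum / Minimum / First / Last | elementary order statistics | mV |
| Total | Σ values × step (pulse area) | mV·µm |
| Average | mean | mV |
| Range | Maximum − Minimum | mV |
| Length | n_samples × step | µm |
| Fill.factor | Total / (Maximum × Length) | — |
| Gradient | mean \|Δvalue\| / step | mV/µm |
| Number.of.cells | count of local maxima with prominence ≥ 0.25 × Range | — |
| Red1Red2.ratio | Total(FL.Red) / Total(X2.FL.Red) | — |

Choices worth noting:

* **Range = Maximum − Minimum** rather than Maximum alone, so the
  descriptor behaves sensibly under a baseline offset.
* **Red1Red2.ratio uses areas**, not maxima — areas are more robust to
  single-sample noise. The denominator-dark case returns a configurable
  cap (default 10⁴) with a warning.
* **Peak prominence 0.25 × Range** for Number.of.cells rejects sampling
  noise while resolving the overlapping bells of simulated colonies; an
  edge-peaked (trigger-truncated) unimodal pulse counts as one cell, a
  flat pulse as zero.

The features obey scale equivariance (intensity × c scales the mV
descriptors by c and leaves Fill.factor, Length and Number.of.cells
unchanged), which the suite property-tests and the trait-level sampler
(below) relies on.

## Preprocessing (`sfcmpipe.preprocess`)

* **Conditional log transform.** Traits with strictly positive minimum
  are replaced by log₁₀ values; base 10 matches the decade-scaled
  conventions of cytometry displays. The flagged set travels with the
  matrix so the transform is exactly invertible and is applied
  consistently at prediction time.
* **Correlation pruning.** Columns are scanned in input order and a
  column is dropped as soon as it correlates (|Pearson r| > 0.8) with a
  retained earlier column. Which member of a pair is dropped is
  inherently arbitrary; dropping the later column makes the result
  deterministic and order-documented. Constant columns have r defined
  as 0 and are retained with a warning.
* **Pooled subsetting.** ⌊target/n_samples⌋ particles per sample,
  uniformly without replacement, so that one clustering represents the
  whole series without being dominated by dense samples. Samples
  smaller than the quota contribute everything they have (with a
  warning) — this is the normal situation in the grouping pass, where
  only ~5% of particles survive cleaning.

## Density-peak clustering (`sfcmpipe.clustering`)

The published workflow uses the flowPeaks algorithm (k-means
over-fitting followed by density-guided merging) with tol = 0.25,
h₀ = 0.05, h = 2. The original package is an R/Bioconductor component;
this module is an independent implementation of the same idea with the
following concrete choices, all behind the `ClusterModel` contract so a
different merging backend could be swapped in:

1. Standardise every dimension (the merge tolerances need a common
   unit; input traits are on mixed log scales).
2. k-means with k₀ = max(8, ⌊√n/2⌋) components (capped at 200),
   k-means++ initialisation, 10 restarts, best inertia.
3. Smooth each component covariance: Σ̃ₖ = h·Sₖ + h₀·Λ, with Λ the
   diagonal of the overall covariance scaled by k₀^(−2/d). The floor
   keeps discrete traits (constant within a component) from collapsing
   the density.
4. Density f(x) = Σ wₖ·N(x; mₖ, Σ̃ₖ), evaluated in log space.
5. Hill-climb from every component mean (gradient ascent with
   backtracking; stop when the step < tol·10⁻² standardised units or
   after 100 iterations).
6. Merge components whose peaks lie within tol of each other **or**
   whose connecting segment (20 sample points) never drops below
   (1 − tol) × the smaller peak density. Both tests are used because
   the published description does not determine which; merging is
   transitive (union-find).
7. Points are assigned to the final cluster of their
   highest-responsibility component — the same rule at fit and predict
   time, so self-assignment is exact. Final clusters are relabelled by
   descending size (cluster 0 is the dominant cluster, which in raw
   field data is the non-cell background).

Acceptance of this reconstruction is behavioural, not bit-compatible
with the original package: exact recovery of well-separated blob
fixtures (ARI = 1 against brute-force nearest-center assignment),
cluster-count monotonicity in h, permutation invariance and determinism
are all tested.

## Forests (`sfcmpipe.forests`)

scikit-learn random forests behind three contracts:

* **Importance ranking** — Gini mean decrease in impurity, descending,
  ties broken lexicographically for bit-reproducibility. 10,001 trees.
* **Cluster classification** — 1,001 trees, out-of-bag error recorded;
  prediction refuses tables missing any training trait and re-applies
  the training-time log transform (zeros clipped at 10⁻¹²; trees only
  use value order, so the clip is harmless).
* **Biovolume regression** — 10,001 trees on **log₁₀ biovolume**, with
  out-of-bag R² defined on that scale. The training panel spans
  13.4–15,478.7 µm³ (three orders of magnitude); a linear-scale fit
  would be dominated entirely by the largest species. Predictions are
  back-transformed to µm³ and inherit the forest-mean property of lying
  within the range of training targets.

Tree counts are odd (vote tie-avoidance). Class imbalance in the
live/other training table (~1:7) is deliberate — it mirrors the rarity
of live cells in field data — and no reweighting is applied.

## Pipeline heuristics (`sfcmpipe.pipeline`)

Two steps that were manual (visual 3-D inspection) in the original
workflow are codified as explicit, logged, overridable rules:

* **Live flagging**: a cluster is live if its median log₁₀
  `FL.Red.Range` exceeds the dimmest cluster's by ≥ 1 dex
  (`live_margin_log10`). Chlorophyll fluorescence is the dominant
  separator between cells and background; 1 dex is far smaller than the
  observed gap (~1.8 dex in the synthetic conditions) yet far larger
  than within-cluster spread. `live_cluster_override` replaces the rule
  with an explicit cluster list.
* **Group assignment** on clusters holding ≥ 5% of the subset, in
  order: (1) lowest `Red1Red2.ratio`, if below `cyano_ratio_max`
  (default 1.5) → cyanobacteria — phycocyanin-rich cells fluoresce
  strongly under the 642 nm laser, making this the one assignment that
  is unambiguous; (2) lowest rank-sum of `X2.FL.Red.Gradient` and
  `FL.Red.First` → cryptophytes; (3) highest remaining ratio →
  green algae; (4) most abundant remainder → chrysophytes. Rules 2–3
  require at least two candidates, so a lone non-cyanobacterial cluster
  falls through to chrysophytes. Ties go to the lower cluster id with a
  warning. Every assignment records its rationale string. The
  non-cyanobacterial rules are heuristics; their thresholds are
  exposed in the configuration and the assignment JSON is meant to be
  reviewed.

Unassigned (< 5%) clusters stay in whole-community totals but are
excluded from per-group totals. Group fractions are computed from
classifier labels on **all** retained particles, not only the clustered
subset.

## Quantification (`sfcmpipe.quantify`)

Aggregation is exact bookkeeping: with group fractions from counts and
arithmetic-mean biovolumes, assigned-group biovolumes plus the
unassigned contribution reconstruct the total to 10⁻⁹ relative (tested).
Validation regresses log₁₀ SFCM estimates on log₁₀ reference estimates
(the reference on the x axis, so slope 1 / intercept 0 is the
ideal-agreement line), reports Pearson r and 95% CIs, substitutes
below-detection zeros in the reference at `substitution_factor` × the
detection limit (default one half), and can exclude points with
hat-matrix leverage above 3 × the average (3·2/n) — a codified version
of the usual "a small number of high-leverage points were excluded",
off by default and reported when on.

## Synthetic data (`sfcmpipe.synthetic`)

The generator stands in for the lab-culture and monitoring-station
datasets the method is normally trained on.

**Species archetypes.** Ten species across five functional groups with
the lab panel's mean biovolumes (13.4, 17.2, 28.7, 31.6, 60.8, 152.7,
226.2, 896.8, 1964.8 and 15,478.7 µm³). Channel amplitude signatures
encode the pigment optics: cyanobacteria strong in 642 nm-stimulated red
(ratio ≈ 0.5), cryptophytes in orange (phycoerythrin) with a narrow
chlorophyll-bearing plastid (low `FL.Red.First`), green algae
chlorophyll-dominated with negligible phycobilins (highest ratio).
One diatom archetype forms 6-cell colonies (modal Number.of.cells = 6),
one cyanobacterium forms filaments with geometric cell counts;
a needle-shaped green alga carries an elongation factor. Signature
contrasts were designed so that the seven field species are mutually
separable (≳ 4 within-component SD in the selected log-trait space) at
the default within-species coefficient of variation of 0.15 — the
"separability dial": raising the cv degrades recovery monotonically
(tested at cv ∈ {0.15, 0.4, 0.8}).

**Pulse level.** Per particle: per-cell Gaussian bells (width = cell
diameter/4 × per-channel factor), amplitude = signature × lognormal ×
(cell volume)^p with p = 2/3 for scatter (cross-section) and 1 for
fluorescence (pigment content), span ∝ cell diameter × cell count,
half-mV-scale additive baseline noise, and trigger truncation of the
ends where sideward scatter < 99.7 mV. Particle biovolume is lognormal
about the species mean; colonies are built of correspondingly smaller
cells so the biovolume distribution stays within the panel's range.

**Trait level.** Field series of 50 × 10,000 particles would be slow to
synthesise pulse-by-pulse, so a vectorised sampler scales each
archetype's *base trait vector* — the per-trait median of 128 featurized
pulses at unit factors, fixed internal seed — by the same per-particle
lognormal factors, using the features' scale-equivariance rules
(amplitude traits × pigment factor, Total × amplitude × length, Gradient
× amplitude / length, Fill.factor and Number.of.cells scale-free), plus
2% multiplicative measurement noise. Anchoring the base vector to
featurized pulses keeps the two paths statistically consistent (tested:
key trait medians agree within ~20%), so forests trained on the
pulse-path lab table transfer to trait-path field data.

**Noise component.** Background signals (bacteria, detritus, electronic
noise) are modelled as a broad lognormal component: low fluorescence
(~3 mV), sideward scatter pinned just above the trigger threshold,
log-SD 1.0, random shape descriptors. No quantitative noise model is
available for real instruments; this construction is ours, and its only
load-bearing property is that it is dim, broad and dominant (95%).

**Field scenario.** Defaults describe the study conditions the pipeline
targets: 50 samples (6 cycling depths, 4-hourly timestamps), 10,000
particles each at 500 µL analysed volume, expected live fraction 5%
with lognormal sample-to-sample variation (σ_log ≈ 0.45), a four-group
community (chrysophytes ≈ 45% of live cells, cryptophytes 20%, green
algae 23%, cyanobacteria declining geometrically from 30% to 1% over
the series so that some samples fall below the 28 cells/mL microscopy
detection limit), and two rare species per group (12–25% within group)
that stay below the 5% cluster-abundance floor. The "microscopy" truth
copy multiplies true densities by lognormal error (cv 0.3, the scale of
count-and-subsample error in sedimentation-chamber counts) and records
zero below the detection limit.

**What passing tests do and do not show.** The generator reproduces the
*statistical structure* the pipeline assumes — separated trait clusters,
pigment-driven group signatures, rare-cell imbalance, paired noisy
reference counts. It does not model optical physics, environmental
plasticity of traits, overlapping or non-Gaussian cluster shapes, or
species absent from the training panel. Synthetic-recovery results
(e.g. out-of-bag errors ≪ 2%, density recovery r ≈ 1) therefore bound
the pipeline's bookkeeping and algorithmic correctness, not its
performance on real communities, where trait overlap and plasticity
dominate the error budget.

## Problem sizes and determinism

The reference study (`sfcmpipe.workflows.run_default_study`, also driven
by `scripts/acceptance.py`) uses the full default conditions: 50 ×
10,000 particles, 100,000-row pooled subset, 10,001/1,001/10,001-tree
forests. The test suite exercises the same code paths at reduced sizes
(12 × 2,000 particles, 20,000-row subsets, a few hundred trees) where
the property under test does not depend on the full scale;
end-to-end determinism is verified at reduced size, and the full-scale
statistics are checked once per session through the shared study
fixture. Every stochastic element — generators, subsetting, k-means,
forests — derives from a single integer seed.

## Known limitations

* The pulse descriptors are reconstructions; instrument-exact parameter
  values will differ (notably `Range` and `Gradient`).
* The flowPeaks-style merging is an independent implementation; cluster
  boundaries can differ from the original R package on ambiguous data.
* Group-assignment rules beyond cyanobacteria are heuristic and should
  be reviewed against the logged rationale on new datasets.
* Whether colonial taxa should be modelled per cell or per particle in
  the biovolume forest is ambiguous; targets here are per particle.
* The noise component and microscopy-error model are constructions, not
  fitted to instrument data.
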