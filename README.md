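# sfcmpipe

Semi-automated analysis of **scanning flow cytometry (SFCM)** data from
phytoplankton communities: data cleaning (gating by clustering instead of
manual polygons), functional-group identification, and estimation of cell
densities and biovolumes at the community and group level.

## Who this is for

Scanning flow cytometers (e.g. CytoSense-class instruments) record a
time-resolved pulse per optical channel for every particle and summarise
each pulse with tens of named parameters (`FL.Red.Range`,
`X2.FL.Red.Gradient`, ...). Automated monitoring stations produce hundreds
of such samples with millions of particles — far beyond what manual
gating can process repeatably. `sfcmpipe` is for aquatic ecologists and
cytometrists who need a scriptable, auditable pipeline from raw particle
tables to per-sample community statistics.

## The method

The pipeline couples lab-culture training data, unsupervised density-peak
clustering and random forests:

1. **Trait selection.** On a labelled lab table (live cells vs other
   signals), log10-transform every trait with positive minimum, drop one
   member of each pair with |Pearson r| > 0.8, rank the survivors by
   random-forest Gini importance (10,001 trees) and keep the top 10.
2. **Cleaning.** Pool an equal number of particles from every field
   sample (~100,000 rows), cluster them on the selected traits with a
   flowPeaks-style algorithm — k-means over-fitting with
   k₀ = max(8, ⌊√n/2⌋) components, Gaussian density smoothing
   Σ̃ₖ = h·Sₖ + h₀·Λ (defaults tol = 0.25, h₀ = 0.05, h = 2), hill
   climbing to density peaks and peak/ridge merging. Clusters whose
   median log₁₀ `FL.Red.Range` (chlorophyll-a proxy) sits ≥ 1 dex above
   the dimmest cluster are flagged as live cells. A 1,001-tree forest
   trained on the cluster labels then classifies every particle of every
   sample; live-cluster members are retained.
3. **Grouping.** The same procedure on the cleaned data with
   group-labelled lab cells and the top 8 traits. Abundant clusters
   (≥ 5% of the subset) are mapped to functional groups by pigment
   heuristics: lowest `Red1Red2.ratio` → cyanobacteria (phycocyanin
   fluoresces under the 642 nm laser), jointly lowest
   `X2.FL.Red.Gradient` and `FL.Red.First` → cryptophytes, highest
   remaining ratio with strong chlorophyll signal → green algae, most
   abundant remainder → chrysophytes.
4. **Quantification.** A 10,001-tree forest regresses log₁₀ biovolume on
   all traits (lab panel spanning 13.4–15,478.7 µm³). Then, per sample:

   - cell density  N = c · 1000 · f_live  (c = particle concentration
     per µL, f_live = retained fraction),
   - group density N_g = N · f_g,
   - total biovolume B = N · V̄, group biovolume B_g = N_g · V̄_g,
     with V̄ the mean predicted per-cell biovolume.

   Validation against paired reference (microscopy-style) counts uses
   ordinary least squares on log₁₀ values, with below-detection zeros
   substituted at half the detection limit and optional exclusion of
   high-leverage points.

Because the instrument datasets the method was developed on are not
shipped here, the package includes a fully specified synthetic generator
(`sfcmpipe.synthetic`): ten species archetypes with the lab panel's mean
biovolumes, pigment-driven channel signatures, pulse-level simulation
with trigger truncation at 99.7 mV sideward scatter, a non-cell noise
component, and multi-sample field series with paired noisy "microscopy"
truth (~5% live cells). See `docs/methods.md` for the model details.

## Worked example

```python
from sfcmpipe import PipelineConfig, run_cleaning, run_grouping, cleaned_samples
from sfcmpipe.synthetic import FieldScenario, generate_field_series, generate_training

samples, truth = generate_field_series(FieldScenario(n_samples=12,
                                                     particles_per_sample=2000,
                                                     seed=7))
train = generate_training(seed=2)          # 1,200 live + 8,400 other lab rows
cfg = PipelineConfig(subset_size=20_000, trees_importance=501,
                     trees_classify=301, random_seed=7)

cleaning = run_cleaning(samples, train.live_other(), cfg)
print(cleaning.clusters.n_clusters, sorted(cleaning.result.live_clusters))
# 8 [1, 2, 3, 4, 5, 6, 7]

grouping = run_grouping(cleaned_samples(samples, cleaning.result),
                        train.groups(), cfg)
print({c: g for c, (g, _) in sorted(grouping.assignment.mapping.items())})
# {0: 'chrysophytes', 1: 'cryptophytes', 2: 'green_algae', 3: 'cyanobacteria',
#  4: 'unassigned', 5: 'unassigned', 6: 'unassigned'}
```

The raw subset resolves into 8 clusters — the noise cluster (cluster 0,
by far the largest) plus seven live-cell clusters flagged by their high
chlorophyll fluorescence. After cleaning, the four abundant clusters map
onto the four functional groups; the three rare species (< 5% of cells)
remain unassigned, as intended.

The same stages are available from the shell:

```bash
sfcmpipe --seed 1 simulate --out particles.csv --truth-out truth.csv
sfcmpipe --seed 1 quantify particles.csv --meta particles_meta.csv --out estimates.csv
sfcmpipe validate estimates.csv truth.csv --detection-limit 28 --out report.json
```

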