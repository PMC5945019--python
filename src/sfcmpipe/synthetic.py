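"""Synthetic scanning-flow-cytometry data with known ground truth.

The generator emulates the statistical structure the pipeline assumes,
at two levels:

* **Pulse level** — per particle, one Gaussian-bell pulse per channel
  (overlapping bells for multi-cell colonies), amplitudes set by a
  species archetype's pigment signature, spatial extent scaling with
  biovolume^(1/3), a small additive baseline noise, and trigger
  truncation at 99.7 mV on sideward scatter.  These pulses feed the
  regular :func:`~sfcmpipe.pulses.featurize` path.

* **Trait level** — a fast vectorised sampler that scales each
  archetype's *base* trait vector (the per-trait median of featurized
  archetype pulses) by per-particle lognormal size and amplitude factors,
  using the same scale-equivariance rules the pulse features obey
  (amplitude traits scale with pigment content, Total with amplitude x
  length, Gradient with amplitude / length, Fill.factor and
  Number.of.cells are scale-free).  This is what makes multi-hundred-
  thousand-particle field series cheap while staying consistent with the
  pulse path.

Ten species archetypes follow the lab-culture panel (mean biovolumes
13.4–15478.7 µm³ across cyanobacteria, green algae, cryptophytes,
chrysophytes and diatoms).  Channel signatures encode the pigment
optics: cyanobacteria fluoresce strongly in the 642 nm-stimulated red
channel (phycocyanin), hence a low Red1Red2.ratio; cryptophytes carry
phycoerythrin (orange); eukaryotes are chlorophyll-dominated.  A
low-fluorescence, high-variance noise component stands in for the
bacteria / detritus / electronic-noise background that dominates raw
field data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .forests import LabeledTraining
from .io import Sample
from .preprocess import TraitMatrix
from .pulses import CHANNELS, ChannelPulse, ParticlePulses, featurize, trait_names

logger = logging.getLogger("sfcmpipe")

TRIGGER_THRESHOLD_MV = 99.7
STEP_UM = 0.5

GROUPS = ("cyanobacteria", "chrysophytes", "cryptophytes", "green_algae", "diatom")

_AMPLITUDE_FEATURES = ("Maximum", "Minimum", "First", "Last", "Average", "Range")


@dataclass
class SpeciesArchetype:
    """Statistical signature of one lab-culture species.

    ``cells`` is ``("fixed", k)`` for unicells/fixed colonies or
    ``("geometric", p)`` for filaments with geometrically distributed
    cell counts.  ``amplitudes`` are mean per-channel pulse heights (mV)
    for a particle at the archetype's mean biovolume; ``width_factors``
    shrink or widen a channel's bell relative to the cell diameter
    (e.g. fluorescence concentrated in a plastid narrower than the
    scatter cross-section).
    """

    name: str
    group: str
    mean_biovolume: float
    cells: tuple = ("fixed", 1)
    amplitudes: dict = field(default_factory=dict)
    width_factors: dict = field(default_factory=dict)
    #: Cell length relative to the volume-equivalent sphere diameter
    #: (> 1 for needle- or spindle-shaped taxa).
    elongation: float = 1.0
    within_species_cv: float = 0.15

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigurationError(f"unknown group {self.group!r}")
        if not self.mean_biovolume > 0:
            raise ConfigurationError("mean_biovolume must be > 0")

    @property
    def typical_cells(self) -> int:
        kind, value = self.cells
        return int(value) if kind == "fixed" else max(1, round(1.0 / value))


@dataclass
class NoiseSignature:
    """Low-fluorescence, high-variance non-cell signal component."""

    amplitudes: dict = field(
        default_factory=lambda: {
            "FWS": 25.0,
            "SWS": 150.0,
            "FL.Red": 3.0,
            "X2.FL.Red": 3.0,
            "FL.Orange": 2.5,
            "FL.Yellow": 2.5,
        }
    )
    log_sigma: float = 1.0


def default_archetypes() -> list:
    """The ten-species lab-culture panel with designed channel signatures."""

    def a(fws, sws, red, x2, orange, yellow):
        return dict(zip(CHANNELS, (fws, sws, red, x2, orange, yellow)))

    narrow_red = {"FL.Red": 0.45}
    return [
        SpeciesArchetype("Synechococcus", "cyanobacteria", 13.4,
                         amplitudes=a(140, 170, 150, 300, 55, 22)),
        SpeciesArchetype("Microcystis", "cyanobacteria", 17.2,
                         amplitudes=a(420, 500, 450, 900, 160, 70)),
        SpeciesArchetype("Chlorella", "green_algae", 28.7,
                         amplitudes=a(220, 190, 300, 14, 45, 90)),
        SpeciesArchetype("Ankistrodesmus", "green_algae", 31.6,
                         amplitudes=a(520, 300, 950, 8, 28, 30), elongation=3.5),
        SpeciesArchetype("Chroomonas", "cryptophytes", 60.8,
                         amplitudes=a(450, 350, 250, 8, 420, 140),
                         width_factors=narrow_red),
        SpeciesArchetype("Synura", "chrysophytes", 152.7,
                         amplitudes=a(800, 600, 400, 20, 90, 260)),
        SpeciesArchetype("Cyclotella", "diatom", 226.2,
                         amplitudes=a(900, 750, 500, 18, 70, 150)),
        SpeciesArchetype("Cryptomonas", "cryptophytes", 896.8,
                         amplitudes=a(1600, 1100, 900, 30, 1300, 420),
                         width_factors={"FL.Red": 0.5}),
        SpeciesArchetype("Asterionella", "diatom", 1964.8, cells=("fixed", 6),
                         amplitudes=a(700, 650, 450, 15, 80, 180)),
        SpeciesArchetype("Anabaena", "cyanobacteria", 15478.7, cells=("geometric", 0.125),
                         amplitudes=a(400, 380, 420, 700, 130, 60)),
    ]


def _draw_cells(archetype: SpeciesArchetype, n: int, rng) -> np.ndarray:
    kind, value = archetype.cells
    if kind == "fixed":
        return np.full(n, int(value))
    if kind == "geometric":
        return np.minimum(rng.geometric(value, size=n), 60)
    raise ConfigurationError(f"unknown cell-count distribution {kind!r}")


def _lognormal(rng, cv: float, size) -> np.ndarray:
    """Mean-1 lognormal multiplier with coefficient of variation ~cv."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size)


def _particle_factors(archetype: SpeciesArchetype, n: int, rng, cv=None):
    """Per-particle biovolume, cell count, length and amplitude factors.

    Shared between the pulse builder and the trait sampler so the two
    paths describe the same population.  Scatter amplitudes scale with
    cross-section (~V^(2/3)), fluorescence with pigment content (~V).
    """
    cv = archetype.within_species_cv if cv is None else cv
    ncells = _draw_cells(archetype, n, rng)
    base_cells = archetype.typical_cells
    # Particle biovolume is lognormal about the species mean; the cell
    # count shapes the pulse (number of bells, span) but longer colonies
    # are built of correspondingly smaller cells, keeping the particle
    # biovolume distribution within the panel's range.
    biovolume = archetype.mean_biovolume * _lognormal(rng, cv, n)
    rel_cell = (biovolume / ncells) / (archetype.mean_biovolume / base_cells)
    # span ~ cell diameter x ncells ~ (V_cell)^(1/3) x ncells
    length_factor = rel_cell ** (1.0 / 3.0) * (ncells / base_cells)
    amp = {}
    for channel in CHANNELS:
        # Pulse height is a per-cell property: scatter scales with the
        # cell cross-section (~V^(2/3)), fluorescence with pigment
        # content (~V), each with independent lognormal variation.
        power = 2.0 / 3.0 if channel in ("FWS", "SWS") else 1.0
        amp[channel] = rel_cell**power * _lognormal(rng, cv, n)
    return biovolume, ncells, length_factor, amp


def _build_particle(pid, archetype, biovolume, ncells, amp_factors, rng,
                    step=STEP_UM, noise_mv=1.0):
    """Construct one particle's 6-channel pulses."""
    cell_d = (6.0 * biovolume / ncells / np.pi) ** (1.0 / 3.0)
    cell_len = cell_d * archetype.elongation
    centers = (np.arange(ncells) + 0.5) * cell_len
    margin = 2.0 + 0.75 * cell_d
    x = np.arange(-margin, ncells * cell_len + margin + step, step)
    raw = {}
    for channel in CHANNELS:
        w = cell_d / 4.0 * archetype.width_factors.get(channel, 1.0)
        bells = np.exp(-((x[:, None] - centers[None, :]) ** 2) / (2.0 * w * w)).sum(axis=1)
        amp = archetype.amplitudes[channel] * amp_factors[channel]
        values = amp * bells + np.abs(rng.normal(0.0, noise_mv, x.size)) + 0.2
        raw[channel] = values
    above = np.nonzero(raw["SWS"] >= TRIGGER_THRESHOLD_MV)[0]
    if above.size == 0:
        peak = int(np.argmax(raw["SWS"]))
        sl = slice(max(0, peak - 1), peak + 2)
    else:
        sl = slice(above[0], above[-1] + 1)
    pulses = {c: ChannelPulse(c, raw[c][sl], step) for c in CHANNELS}
    return ParticlePulses(pid, pulses)


def generate_pulses(archetype: SpeciesArchetype, n: int, seed) -> list:
    """Generate ``n`` particles of an archetype as raw 6-channel pulses."""
    particles, _ = generate_pulses_with_truth(archetype, n, seed)
    return particles


def generate_pulses_with_truth(archetype: SpeciesArchetype, n: int, seed,
                               cv=None, prefix: str = "p"):
    """As :func:`generate_pulses`, also returning per-particle truth.

    Returns ``(particles, truth)`` where ``truth`` holds the biovolume
    (µm³) and cell count actually used for each particle.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    biovolume, ncells, _, amp = _particle_factors(archetype, n, rng, cv=cv)
    particles = []
    for i in range(n):
        amps_i = {c: amp[c][i] for c in CHANNELS}
        particles.append(
            _build_particle(f"{prefix}{i:06d}", archetype, biovolume[i],
                            int(ncells[i]), amps_i, rng)
        )
    truth = pd.DataFrame(
        {"biovolume_um3": biovolume, "n_cells": ncells},
        index=[p.particle_id for p in particles],
    )
    return particles, truth


_BASE_CACHE: dict = {}


def archetype_base_traits(archetype: SpeciesArchetype, n_calibration: int = 128) -> pd.Series:
    """Median featurized trait vector of an archetype at unit factors.

    Computed from ``n_calibration`` pulses with size/amplitude variation
    switched off (cv = 0) and a fixed internal seed, so only pulse
    construction and measurement noise contribute.  This anchors the
    fast trait sampler to the pulse path.
    """
    key = (archetype.name, archetype.mean_biovolume, tuple(sorted(archetype.amplitudes.items())),
           tuple(sorted(archetype.width_factors.items())), archetype.cells,
           archetype.elongation, n_calibration)
    if key not in _BASE_CACHE:
        particles, _ = generate_pulses_with_truth(
            archetype, n_calibration, seed=np.random.default_rng(1234), cv=0.0
        )
        rows = pd.DataFrame([featurize(p).traits for p in particles])
        _BASE_CACHE[key] = rows.median(axis=0)
    return _BASE_CACHE[key]


def sample_traits(archetype: SpeciesArchetype, n: int, rng, cv=None,
                  measurement_cv: float = 0.02):
    """Vectorised trait-level sampler for one archetype.

    Returns ``(traits, truth)``: an ``n x 67`` DataFrame plus the
    per-particle biovolume/cell-count truth.  Scaling rules mirror the
    scale equivariance of the pulse features.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    base = archetype_base_traits(archetype)
    biovolume, ncells, length_factor, amp = _particle_factors(archetype, n, rng, cv=cv)
    cols = {}
    for channel in CHANNELS:
        g = amp[channel]
        for feat in _AMPLITUDE_FEATURES:
            cols[f"{channel}.{feat}"] = base[f"{channel}.{feat}"] * g
        cols[f"{channel}.Total"] = base[f"{channel}.Total"] * g * length_factor
        cols[f"{channel}.Length"] = base[f"{channel}.Length"] * length_factor
        cols[f"{channel}.Gradient"] = base[f"{channel}.Gradient"] * g / length_factor
        ff = base[f"{channel}.Fill.factor"] * _lognormal(rng, 0.03, n)
        cols[f"{channel}.Fill.factor"] = np.clip(ff, 0.0, 1.0)
        cols[f"{channel}.Number.of.cells"] = ncells.astype(float)
    frame = pd.DataFrame(cols)
    if measurement_cv > 0:
        scale_cols = [c for c in frame.columns if not c.endswith("Number.of.cells")
                      and not c.endswith("Fill.factor")]
        frame[scale_cols] = frame[scale_cols] * _lognormal(
            rng, measurement_cv, (n, len(scale_cols))
        )
    frame["Red1Red2.ratio"] = frame["FL.Red.Total"] / frame["X2.FL.Red.Total"]
    frame = frame[trait_names()]
    truth = pd.DataFrame({"biovolume_um3": biovolume, "n_cells": ncells})
    return frame, truth


def sample_noise_traits(n: int, rng, signature: NoiseSignature | None = None) -> pd.DataFrame:
    """Vectorised trait sampler for the non-cell background component."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sig = signature or NoiseSignature()
    cols = {}
    length = np.exp(rng.normal(np.log(3.0), 0.6, n))
    for channel in CHANNELS:
        peak = sig.amplitudes[channel] * np.exp(rng.normal(0.0, sig.log_sigma, n))
        if channel == "SWS":
            peak = TRIGGER_THRESHOLD_MV + np.abs(peak - TRIGGER_THRESHOLD_MV) + 1.0
        minimum = peak * rng.uniform(0.05, 0.35, n)
        average = minimum + (peak - minimum) * rng.uniform(0.3, 0.7, n)
        cols[f"{channel}.Maximum"] = peak
        cols[f"{channel}.Minimum"] = minimum
        cols[f"{channel}.First"] = minimum * rng.uniform(0.8, 1.2, n)
        cols[f"{channel}.Last"] = minimum * rng.uniform(0.8, 1.2, n)
        cols[f"{channel}.Range"] = peak - minimum
        cols[f"{channel}.Average"] = average
        cols[f"{channel}.Total"] = average * length
        cols[f"{channel}.Length"] = length
        cols[f"{channel}.Gradient"] = (peak - minimum) / length * rng.uniform(0.5, 1.5, n)
        cols[f"{channel}.Fill.factor"] = rng.uniform(0.2, 0.8, n)
        cols[f"{channel}.Number.of.cells"] = rng.choice(
            [0.0, 1.0, 2.0], size=n, p=[0.3, 0.5, 0.2]
        )
    frame = pd.DataFrame(cols)
    frame["Red1Red2.ratio"] = frame["FL.Red.Total"] / frame["X2.FL.Red.Total"]
    return frame[trait_names()]


def generate_noise_pulses(n: int, rng, signature: NoiseSignature | None = None) -> list:
    """Raw-pulse version of the background component (for the lab path)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sig = signature or NoiseSignature()
    particles = []
    for i in range(n):
        length = max(3, int(np.exp(rng.normal(np.log(8.0), 0.5))))
        pulses = {}
        for channel in CHANNELS:
            amp = sig.amplitudes[channel] * np.exp(rng.normal(0.0, sig.log_sigma))
            if channel == "SWS":
                amp = TRIGGER_THRESHOLD_MV + abs(amp - TRIGGER_THRESHOLD_MV) + 5.0
            bumps = np.abs(rng.normal(0.6, 0.3, length))
            values = amp * np.convolve(bumps, [0.25, 0.5, 0.25], mode="same") + 0.2
            if channel == "SWS":
                values = np.maximum(values, TRIGGER_THRESHOLD_MV + 0.5)
            pulses[channel] = ChannelPulse(channel, values, STEP_UM)
        particles.append(ParticlePulses(f"noise{i:06d}", pulses))
    return particles


@dataclass
class TrainingSet:
    """Lab-culture training table with live/other, group and biovolume labels."""

    matrix: TraitMatrix
    labels: pd.DataFrame  # columns: label, group, species, biovolume_um3

    def live_other(self) -> LabeledTraining:
        return LabeledTraining(self.matrix, self.labels["label"])

    def _live_subset(self) -> TraitMatrix:
        mask = (self.labels["label"] == "live").to_numpy()
        return TraitMatrix(
            self.matrix.data.loc[mask].copy(), transform_log=set(self.matrix.transform_log)
        )

    def groups(self) -> LabeledTraining:
        mask = (self.labels["label"] == "live").to_numpy()
        return LabeledTraining(self._live_subset(), self.labels.loc[mask, "group"])

    def biovolume(self) -> LabeledTraining:
        mask = (self.labels["label"] == "live").to_numpy()
        return LabeledTraining(self._live_subset(), self.labels.loc[mask, "biovolume_um3"])


def generate_training(
    n_live: int = 1200,
    n_other: int = 8400,
    archetypes=None,
    seed=0,
    mode: str = "pulses",
) -> TrainingSet:
    """Generate the lab-culture training table.

    Defaults mirror a realistic lab campaign: ~1,200 live-cell rows drawn
    equally across the ten archetypes and ~8,400 background rows, a
    ~1:7 mix chosen to resemble the low live-cell share of field data.
    ``mode="pulses"`` (default) runs every particle through the full
    pulse -> featurize path; ``mode="traits"`` uses the fast sampler.
    """
    archetypes = list(archetypes) if archetypes is not None else default_archetypes()
    if len({a.group for a in archetypes}) < 2:
        raise ConfigurationError("training archetypes must span >= 2 groups")
    rng = np.random.default_rng(seed)
    per = np.full(len(archetypes), n_live // len(archetypes))
    per[: n_live - per.sum()] += 1

    rows = []
    meta = []
    for archetype, count in zip(archetypes, per):
        if count == 0:
            continue
        if mode == "pulses":
            particles, truth = generate_pulses_with_truth(
                archetype, int(count), rng, prefix=f"{archetype.name}_"
            )
            frame = pd.DataFrame([featurize(p).traits for p in particles])
            biovols = truth["biovolume_um3"].to_numpy()
        elif mode == "traits":
            frame, truth = sample_traits(archetype, int(count), rng)
            biovols = truth["biovolume_um3"].to_numpy()
        else:
            raise ConfigurationError(f"unknown mode {mode!r}")
        rows.append(frame.reset_index(drop=True))
        meta.append(
            pd.DataFrame(
                {
                    "label": "live",
                    "group": archetype.group,
                    "species": archetype.name,
                    "biovolume_um3": biovols,
                }
            )
        )
    if mode == "pulses":
        noise_particles = generate_noise_pulses(n_other, rng)
        noise_frame = pd.DataFrame([featurize(p).traits for p in noise_particles])
    else:
        noise_frame = sample_noise_traits(n_other, rng)
    rows.append(noise_frame.reset_index(drop=True))
    meta.append(
        pd.DataFrame(
            {
                "label": ["other"] * n_other,
                "group": pd.NA,
                "species": pd.NA,
                "biovolume_um3": np.nan,
            }
        )
    )
    data = pd.concat(rows, ignore_index=True)
    labels = pd.concat(meta, ignore_index=True)
    index = pd.Index([f"lab{i:06d}" for i in range(len(data))], name="particle_id")
    data.index = index
    labels.index = index
    logger.info(
        "generate_training: %d live + %d other rows, %d traits (%s mode)",
        int((labels["label"] == "live").sum()), n_other, data.shape[1], mode,
    )
    return TrainingSet(TraitMatrix(data), labels)


@dataclass
class FieldScenario:
    """Layout of a synthetic monitoring campaign.

    Defaults describe the study conditions the pipeline targets: 50
    depth-resolved samples of 10,000 particles, ~5% live cells, a
    four-group community whose cyanobacteria decline over the series
    (so some samples fall below a microscopy detection limit), and a
    paired "microscopy" truth copy perturbed by lognormal error.
    """

    n_samples: int = 50
    particles_per_sample: int = 10_000
    live_fraction: float = 0.05
    live_fraction_sigma: float = 0.45
    base_composition: dict = field(
        default_factory=lambda: {
            "chrysophytes": 0.45,
            "cryptophytes": 0.20,
            "green_algae": 0.23,
            "cyanobacteria": 0.12,
        }
    )
    cyano_start: float = 0.30
    cyano_end: float = 0.01
    species_split: dict = field(
        default_factory=lambda: {
            "chrysophytes": {"Synura": 1.0},
            "cryptophytes": {"Chroomonas": 0.85, "Cryptomonas": 0.15},
            "cyanobacteria": {"Synechococcus": 0.75, "Microcystis": 0.25},
            "green_algae": {"Chlorella": 0.85, "Ankistrodesmus": 0.15},
        }
    )
    composition_jitter_cv: float = 0.25
    within_species_cv: float = 0.15
    noise_component: NoiseSignature = field(default_factory=NoiseSignature)
    microscopy_error_cv: float = 0.3
    detection_limit_cells_per_ml: float = 28.0
    volume_analyzed_ul: float = 500.0
    depths_m: tuple = (1.0, 2.5, 4.0, 5.5, 7.0, 8.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.live_fraction < 1):
            raise ConfigurationError("live_fraction must lie in (0, 1)")
        total = sum(self.base_composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("base_composition must sum to 1")
        for group, split in self.species_split.items():
            if group not in self.base_composition:
                raise ConfigurationError(f"species_split for unknown group {group!r}")
            if abs(sum(split.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"species_split[{group!r}] must sum to 1")

    def composition(self, index: int) -> dict:
        """Expected group fractions of live cells for sample ``index``."""
        frac = np.exp(
            np.log(self.cyano_start)
            + (np.log(self.cyano_end) - np.log(self.cyano_start))
            * (index / max(1, self.n_samples - 1))
        )
        others = {g: f for g, f in self.base_composition.items() if g != "cyanobacteria"}
        scale = (1.0 - frac) / sum(others.values())
        comp = {g: f * scale for g, f in others.items()}
        comp["cyanobacteria"] = frac
        return comp


def generate_field_series(scenario: FieldScenario | None = None, archetypes=None):
    """Generate a paired (SFCM samples, truth table) field series.

    The truth table is long-format: one row per sample x group plus a
    ``total`` row, holding the exact per-sample cell densities
    (cells/mL) and biovolumes (µm³/mL) alongside a noisy "microscopy"
    copy (lognormal error, zero below the detection limit).  Group truth
    densities plus the noise density sum exactly to the particle
    concentration x 1000.
    """
    scenario = scenario or FieldScenario()
    archetypes = list(archetypes) if archetypes is not None else default_archetypes()
    by_name = {a.name: a for a in archetypes}
    for split in scenario.species_split.values():
        missing = [s for s in split if s not in by_name]
        if missing:
            raise ConfigurationError(f"species_split references unknown archetypes {missing}")

    rng = np.random.default_rng(scenario.seed)
    n = scenario.particles_per_sample
    conc_per_ul = n / scenario.volume_analyzed_ul
    total_particle_density = conc_per_ul * 1000.0

    samples = []
    truth_rows = []
    t0 = pd.Timestamp("2014-08-17T00:00:00")
    groups = list(scenario.base_composition)
    for j in range(scenario.n_samples):
        sid = f"s{j:03d}"
        depth = scenario.depths_m[j % len(scenario.depths_m)]
        timestamp = (t0 + pd.Timedelta(hours=4 * j)).isoformat()

        sigma = scenario.live_fraction_sigma
        lf = scenario.live_fraction * np.exp(rng.normal(-0.5 * sigma**2, sigma))
        lf = float(np.clip(lf, 1e-4, 0.5))
        comp = scenario.composition(j)
        jitter = {
            g: comp[g] * _lognormal(rng, scenario.composition_jitter_cv, 1)[0]
            for g in groups
        }
        norm = sum(jitter.values())
        comp = {g: v / norm for g, v in jitter.items()}

        species_probs = []
        species_list = []
        for g in groups:
            for sp, w in scenario.species_split[g].items():
                species_list.append(sp)
                species_probs.append(lf * comp[g] * w)
        probs = np.array([1.0 - lf] + species_probs)
        counts = rng.multinomial(n, probs / probs.sum())
        n_noise, species_counts = counts[0], counts[1:]

        frames = [sample_noise_traits(n_noise, rng, scenario.noise_component)]
        origins = ["noise"] * n_noise
        biovols = [np.full(n_noise, np.nan)]
        for sp, count in zip(species_list, species_counts):
            if count == 0:
                continue
            arch = replace(by_name[sp], within_species_cv=scenario.within_species_cv)
            frame, truth = sample_traits(arch, int(count), rng)
            frames.append(frame)
            origins.extend([sp] * count)
            biovols.append(truth["biovolume_um3"].to_numpy())

        data = pd.concat(frames, ignore_index=True)
        origin = np.array(origins)
        biovolume = np.concatenate(biovols)
        order = rng.permutation(len(data))
        data = data.iloc[order].reset_index(drop=True)
        origin = origin[order]
        biovolume = biovolume[order]
        data.index = pd.Index([f"{sid}_p{i:05d}" for i in range(len(data))],
                              name="particle_id")
        samples.append(
            Sample(
                sample_id=sid,
                traits=data,
                depth_m=depth,
                timestamp=timestamp,
                volume_analyzed_ul=scenario.volume_analyzed_ul,
                particle_concentration_per_ul=conc_per_ul,
            )
        )

        group_of = {sp: g for g in groups for sp in scenario.species_split[g]}
        live_mask = origin != "noise"
        n_live = int(live_mask.sum())
        rows = {}
        for g in groups:
            mask = np.isin(origin, [sp for sp, gg in group_of.items() if gg == g])
            density = total_particle_density * mask.sum() / n
            bio = float(biovolume[mask].mean()) * density if mask.any() else 0.0
            rows[g] = (density, bio)
        total_density = total_particle_density * n_live / n
        total_bio = float(biovolume[live_mask].mean()) * total_density if n_live else 0.0
        rows["total"] = (total_density, total_bio)
        rows["noise"] = (total_particle_density * n_noise / n, np.nan)
        for name, (density, bio) in rows.items():
            if name == "noise":
                mic_density = mic_bio = np.nan
            else:
                err = _lognormal(rng, scenario.microscopy_error_cv, 2)
                mic_density = density * err[0]
                mic_bio = bio * err[1]
                if mic_density < scenario.detection_limit_cells_per_ml:
                    mic_density = 0.0
                    mic_bio = 0.0
            truth_rows.append(
                {
                    "sample_id": sid,
                    "group": name,
                    "true_density_per_ml": density,
                    "true_biovolume_um3_per_ml": bio,
                    "microscopy_density_per_ml": mic_density,
                    "microscopy_biovolume_um3_per_ml": mic_bio,
                }
            )

    truth = pd.DataFrame(truth_rows)
    logger.info(
        "generate_field_series: %d samples x %d particles, pooled live fraction %.4f",
        scenario.n_samples,
        n,
        truth.loc[truth["group"] == "total", "true_density_per_ml"].sum()
        / (total_particle_density * scenario.n_samples),
    )
    return samples, truth
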