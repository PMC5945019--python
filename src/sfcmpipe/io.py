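"""Canonical data model and CSV I/O.

The on-disk format is deliberately plain: a rectangular particle CSV
(one row per particle, header = dotted trait names exactly as the
instrument prints them, plus ``particle_id`` and ``sample_id`` columns)
and a side-car metadata CSV keyed by ``sample_id`` carrying depth,
timestamp, volume analyzed and particle concentration.  Vendor binary
exports are intentionally not parsed; export to CSV first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, IntegrityError, ParseError

logger = logging.getLogger("sfcmpipe")

ID_COLUMNS = ("particle_id", "sample_id")

#: Columns of the community-estimate CSV written by :func:`write_estimates`.
ESTIMATE_COLUMNS = ("sample_id", "group", "cell_density_per_mL", "biovolume_um3_per_mL")


@dataclass
class ParticleRecord:
    """Named scalar trait values plus particle/sample identity.

    Trait names follow the dotted instrument convention
    (``FL.Red.Range``); values are finite numbers (mV, mV·µm, µm or
    dimensionless depending on the trait).
    """

    particle_id: str
    sample_id: str
    traits: dict

    def __post_init__(self) -> None:
        vals = np.asarray(list(self.traits.values()), dtype=float)
        if vals.size and not np.all(np.isfinite(vals)):
            bad = [k for k, v in self.traits.items() if not np.isfinite(v)]
            raise DomainError(f"particle {self.particle_id}: non-finite traits {bad}")


@dataclass
class Sample:
    """One measurement: a set of particles plus acquisition metadata.

    Particle traits are stored as a DataFrame (index = particle_id,
    columns = trait names) so that multi-hundred-thousand-particle series
    stay vectorised; :meth:`records` yields :class:`ParticleRecord`
    objects on demand.
    """

    sample_id: str
    traits: pd.DataFrame
    depth_m: float | None = None
    timestamp: str | None = None
    volume_analyzed_ul: float | None = None
    particle_concentration_per_ul: float | None = None
    #: Set False on derived samples (e.g. cleaned subsets) where the
    #: instrument concentration intentionally no longer matches count/volume.
    check_concentration: bool = True

    def __post_init__(self) -> None:
        if self.volume_analyzed_ul is not None and not self.volume_analyzed_ul > 0:
            raise IntegrityError(f"{self.sample_id}: volume_analyzed must be > 0")
        if (
            self.particle_concentration_per_ul is not None
            and self.particle_concentration_per_ul < 0
        ):
            raise IntegrityError(f"{self.sample_id}: particle concentration < 0")
        if self.traits.index.has_duplicates:
            dupes = self.traits.index[self.traits.index.duplicated()].unique().tolist()
            raise IntegrityError(
                f"{self.sample_id}: duplicate particle_id(s) {dupes[:5]}"
            )
        # When both count/volume and a concentration are supplied they
        # must agree (relative deviation < 1e-6).
        if (
            self.check_concentration
            and self.particle_concentration_per_ul is not None
            and self.volume_analyzed_ul is not None
            and len(self.traits) > 0
        ):
            implied = len(self.traits) / self.volume_analyzed_ul
            if self.particle_concentration_per_ul > 0:
                dev = abs(implied - self.particle_concentration_per_ul) / max(
                    self.particle_concentration_per_ul, 1e-300
                )
                if dev > 1e-6:
                    raise IntegrityError(
                        f"{self.sample_id}: particle_concentration "
                        f"{self.particle_concentration_per_ul}/µL inconsistent with "
                        f"count/volume {implied:.6g}/µL"
                    )

    @property
    def n_particles(self) -> int:
        return len(self.traits)

    def records(self) -> Iterable[ParticleRecord]:
        for pid, row in self.traits.iterrows():
            yield ParticleRecord(str(pid), self.sample_id, row.to_dict())

    @classmethod
    def from_records(cls, sample_id: str, records: Iterable[ParticleRecord], **meta) -> "Sample":
        records = list(records)
        frame = pd.DataFrame(
            [r.traits for r in records], index=[r.particle_id for r in records]
        )
        return cls(sample_id=sample_id, traits=frame, **meta)


def _check_numeric(frame: pd.DataFrame, path) -> None:
    if frame.empty:
        return
    trait_cols = [c for c in frame.columns if c not in ID_COLUMNS]
    for col in trait_cols:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = frame.index[coerced.isna() & frame[col].notna()]
            if len(bad):
                raise ParseError(
                    f"{path}: non-numeric value in column '{col}', row {int(bad[0])}"
                )
            frame[col] = coerced


def read_sample_table(path, meta=None) -> list:
    """Read a particle CSV into a list of :class:`Sample`.

    Parameters
    ----------
    path:
        Particle CSV with a header row; must contain ``particle_id`` and
        ``sample_id`` columns, every other column is a trait.
    meta:
        Optional metadata source: path to a side-car CSV keyed by
        ``sample_id`` (columns ``depth_m``, ``timestamp``,
        ``volume_analyzed_ul``, ``particle_concentration_per_ul``), or an
        equivalent DataFrame / mapping.

    Samples are returned grouped by ``sample_id`` in order of first
    appearance; trait names and row order are preserved verbatim.
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file, no header row") from exc
    missing = [c for c in ID_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    _check_numeric(frame, path)

    meta_table: pd.DataFrame | None = None
    if meta is not None:
        if isinstance(meta, (str, Path)):
            meta_table = pd.read_csv(meta)
        elif isinstance(meta, pd.DataFrame):
            meta_table = meta
        elif isinstance(meta, Mapping):
            meta_table = pd.DataFrame(meta).T.rename_axis("sample_id").reset_index()
        else:
            raise FormatError(f"unsupported metadata source {type(meta)!r}")
        if "sample_id" not in meta_table.columns:
            raise FormatError("metadata table lacks a sample_id column")
        meta_table = meta_table.set_index(meta_table["sample_id"].astype(str))

    if frame.empty:
        logger.warning("%s: header-only particle table, no particles", path)

    samples = []
    frame["sample_id"] = frame["sample_id"].astype(str)
    for sid, chunk in frame.groupby("sample_id", sort=False):
        traits = chunk.drop(columns=list(ID_COLUMNS))
        traits.index = chunk["particle_id"].astype(str)
        traits.index.name = "particle_id"
        kwargs = {}
        if meta_table is not None and sid in meta_table.index:
            row = meta_table.loc[sid]
            for key in (
                "depth_m",
                "timestamp",
                "volume_analyzed_ul",
                "particle_concentration_per_ul",
            ):
                if key in row and pd.notna(row[key]):
                    kwargs[key] = row[key] if key == "timestamp" else float(row[key])
        samples.append(Sample(sample_id=str(sid), traits=traits, **kwargs))
    logger.info("%s: read %d particles in %d samples", path, len(frame), len(samples))
    return samples


def write_sample_table(samples: Iterable[Sample], path, meta_path=None):
    """Write samples back to a particle CSV (and optional metadata CSV)."""
    frames = []
    meta_rows = []
    for s in samples:
        chunk = s.traits.copy()
        chunk.insert(0, "sample_id", s.sample_id)
        chunk.insert(0, "particle_id", chunk.index)
        frames.append(chunk)
        meta_rows.append(
            {
                "sample_id": s.sample_id,
                "depth_m": s.depth_m,
                "timestamp": s.timestamp,
                "volume_analyzed_ul": s.volume_analyzed_ul,
                "particle_concentration_per_ul": s.particle_concentration_per_ul,
            }
        )
    table = pd.concat(frames, axis=0) if frames else pd.DataFrame(columns=ID_COLUMNS)
    table.to_csv(path, index=False)
    if meta_path is not None:
        pd.DataFrame(meta_rows).to_csv(meta_path, index=False)
    return path


def write_estimates(estimates, path):
    """Write community estimates to CSV, one row per sample x group.

    Each sample contributes one row per functional group plus a
    ``total`` pseudo-group row; the round trip through
    :func:`read_estimates` is lossless to float precision.
    """
    estimates = list(estimates)
    if not estimates:
        raise DomainError("write_estimates: empty estimate collection")
    rows = []
    for est in estimates:
        rows.append(
            {
                "sample_id": est.sample_id,
                "group": "total",
                "cell_density_per_mL": est.total_density,
                "biovolume_um3_per_mL": est.total_biovolume,
            }
        )
        for group in sorted(est.group_density):
            rows.append(
                {
                    "sample_id": est.sample_id,
                    "group": group,
                    "cell_density_per_mL": est.group_density[group],
                    "biovolume_um3_per_mL": est.group_biovolume.get(group, 0.0),
                }
            )
    pd.DataFrame(rows, columns=list(ESTIMATE_COLUMNS)).to_csv(path, index=False)
    return path


def read_estimates(path) -> pd.DataFrame:
    """Read an estimates CSV written by :func:`write_estimates`."""
    frame = pd.read_csv(path)
    missing = [c for c in ESTIMATE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing estimate column(s) {missing}")
    return frame


def read_pulses(path) -> list:
    """Read raw pulses from a long-format CSV.

    Expected columns: ``particle_id, channel, index, value`` and
    optionally ``step`` (µm per sample, default 0.5).  Returns a list of
    :class:`~sfcmpipe.pulses.ParticlePulses`.
    """
    from .pulses import CHANNELS, ChannelPulse, ParticlePulses

    frame = pd.read_csv(path)
    required = {"particle_id", "channel", "index", "value"}
    if not required.issubset(frame.columns):
        raise FormatError(f"{path}: pulse CSV needs columns {sorted(required)}")
    particles = []
    for pid, chunk in frame.groupby("particle_id", sort=False):
        pulses = {}
        step = float(chunk["step"].iloc[0]) if "step" in chunk else 0.5
        for channel, series in chunk.groupby("channel", sort=False):
            series = series.sort_values("index")
            pulses[str(channel)] = ChannelPulse(
                str(channel), series["value"].to_numpy(), step
            )
        missing = [c for c in CHANNELS if c not in pulses]
        if missing:
            raise FormatError(f"{path}: particle {pid} missing channels {missing}")
        particles.append(ParticlePulses(str(pid), pulses))
    return particles


def write_pulses(particles, path):
    """Write pulses to the long-format CSV read by :func:`read_pulses`."""
    rows = []
    for particle in particles:
        for channel, pulse in particle.pulses.items():
            for i, value in enumerate(pulse.values):
                rows.append(
                    {
                        "particle_id": particle.particle_id,
                        "channel": channel,
                        "index": i,
                        "value": value,
                        "step": pulse.step,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
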