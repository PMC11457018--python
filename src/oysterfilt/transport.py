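"""Particle tracks, per-cell environments, cell geometry: readers and validation.

This module is the seam between the filtration model and whatever produced
the transport fields — a hydrodynamic model with Lagrangian particle
tracking in the original application, the synthetic estuary generator here.
Everything is plain delimited text:

* tracks:      particle_id, step_index, cell_id   (cell_id may be OUTSIDE)
* environment: cell_id, step_index, temperature_c, salinity_ppt
               [, do_mg_l, tss_mg_l]
* geometry:    cell_id, surface_area_m2, volume_m3

Occupancy is dense: every (particle, step) pair must be present, with the
distinguished value OUTSIDE for particles beyond the model boundary (their
load is untouched while outside).  Step indices are 0-based and contiguous;
step k covers simulated hours [k·Δt, (k+1)·Δt), and environmental values
are piecewise-constant within a step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .bioenergetics import AbioticState

__all__ = [
    "OUTSIDE",
    "CellGeometry",
    "ParticleTrackSet",
    "CellEnvironmentSeries",
    "ValidationReport",
    "TrackFormatError",
    "DomainValidationError",
    "read_particle_tracks",
    "write_particle_tracks",
    "read_cell_environment",
    "write_cell_environment",
    "read_geometry",
    "write_geometry",
    "validate_domain",
]

#: Distinguished occupancy value for particles beyond the model boundary.
OUTSIDE = "OUTSIDE"
_OUTSIDE_CODE = -1


class TrackFormatError(ValueError):
    """A track/environment/geometry table violates its format contract."""


class DomainValidationError(ValueError):
    """Tracks, environment and geometry are mutually inconsistent."""


@dataclass(frozen=True)
class CellGeometry:
    """Surface area (m²) and water volume (m³) of one grid cell."""

    cell_id: str
    surface_area: float
    volume: float

    def __post_init__(self) -> None:
        if self.surface_area <= 0:
            raise ValueError(f"surface_area must be > 0 (cell {self.cell_id})")
        if self.volume <= 0:
            raise ValueError(f"volume must be > 0 (cell {self.cell_id})")


@dataclass
class ParticleTrackSet:
    """Dense hourly cell occupancy for a set of tracked particles.

    ``occupancy`` holds integer codes: an index into ``cell_ids`` or −1 for
    OUTSIDE.  Shape (n_particles, n_steps).
    """

    cell_ids: list[str]
    occupancy: np.ndarray
    step_duration: float = 1.0

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=np.int32)
        if self.occupancy.ndim != 2:
            raise ValueError("occupancy must be 2-D (particles × steps)")
        if self.step_duration <= 0:
            raise ValueError("step_duration must be > 0 hours")
        if self.occupancy.size and (
            self.occupancy.min() < _OUTSIDE_CODE
            or self.occupancy.max() >= len(self.cell_ids)
        ):
            raise ValueError("occupancy codes out of range for cell_ids")

    @property
    def n_particles(self) -> int:
        return self.occupancy.shape[0]

    @property
    def n_steps(self) -> int:
        return self.occupancy.shape[1]

    def cell_id_at(self, particle: int, step: int) -> str:
        """Cell id occupied by `particle` at `step` (or OUTSIDE)."""
        code = self.occupancy[particle, step]
        return OUTSIDE if code == _OUTSIDE_CODE else self.cell_ids[code]

    def referenced_cell_ids(self) -> set[str]:
        """Cell ids actually occupied at least once."""
        codes = np.unique(self.occupancy)
        return {self.cell_ids[c] for c in codes if c != _OUTSIDE_CODE}


@dataclass
class CellEnvironmentSeries:
    """Per-cell, per-step abiotic conditions as dense arrays.

    ``temperature`` and ``salinity`` have shape (n_cells, n_steps); the
    optional ``dissolved_oxygen`` and ``seston`` arrays are None when the
    source lacked those columns.
    """

    cell_ids: list[str]
    temperature: np.ndarray
    salinity: np.ndarray
    dissolved_oxygen: Optional[np.ndarray] = None
    seston: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.salinity = np.asarray(self.salinity, dtype=float)
        n = (len(self.cell_ids), self.n_steps)
        for name in ("temperature", "salinity", "dissolved_oxygen", "seston"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            setattr(self, name, arr)
            if arr.shape != n:
                raise ValueError(f"{name} must have shape {n}, got {arr.shape}")
        if np.any(self.salinity < 0):
            raise ValueError("salinity must be >= 0 everywhere")
        self._index = {c: i for i, c in enumerate(self.cell_ids)}

    @property
    def n_steps(self) -> int:
        return self.temperature.shape[1]

    def row(self, cell_id: str) -> int:
        return self._index[cell_id]

    def state(self, cell_id: str, step: int) -> AbioticState:
        """The AbioticState of one cell at one step."""
        i = self._index[cell_id]
        return AbioticState(
            temperature=float(self.temperature[i, step]),
            salinity=float(self.salinity[i, step]),
            dissolved_oxygen=None
            if self.dissolved_oxygen is None
            else float(self.dissolved_oxygen[i, step]),
            seston=None if self.seston is None else float(self.seston[i, step]),
        )


@dataclass
class ValidationReport:
    """Findings from cross-validating tracks, geometry and environment."""

    findings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def __str__(self) -> str:
        if self.ok:
            return "domain consistent: no findings"
        return "\n".join(f"- {f}" for f in self.findings)

    def raise_if_failed(self) -> None:
        if not self.ok:
            raise DomainValidationError(str(self))


# ---------------------------------------------------------------- tracks IO


def read_particle_tracks(
    source: Union[str, Path], step_duration: float = 1.0
) -> ParticleTrackSet:
    """Read a track table (CSV: particle_id, step_index, cell_id).

    The table must be dense: every particle must have exactly one row for
    every step index 0..n_steps−1.  Missing pairs, duplicates or
    non-contiguous step indices raise :class:`TrackFormatError`.
    """
    df = pd.read_csv(source, dtype={"cell_id": str})
    required = ["particle_id", "step_index", "cell_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrackFormatError(f"track table missing columns {missing}")
    if df.empty:
        raise TrackFormatError("track table is empty")
    if df.duplicated(["particle_id", "step_index"]).any():
        raise TrackFormatError("duplicate (particle_id, step_index) rows")

    steps = np.sort(df["step_index"].unique())
    n_steps = len(steps)
    if not np.array_equal(steps, np.arange(n_steps)):
        raise TrackFormatError(
            "step indices must be contiguous 0..n_steps-1; got "
            f"{steps[:5].tolist()}..."
        )
    particles = np.sort(df["particle_id"].unique())
    n_particles = len(particles)
    if len(df) != n_particles * n_steps:
        raise TrackFormatError(
            "track table is not dense: expected "
            f"{n_particles * n_steps} rows, got {len(df)}"
        )

    cell_ids = sorted(set(df["cell_id"]) - {OUTSIDE})
    code = {c: i for i, c in enumerate(cell_ids)}
    code[OUTSIDE] = _OUTSIDE_CODE
    pidx = {p: i for i, p in enumerate(particles)}
    occupancy = np.empty((n_particles, n_steps), dtype=np.int32)
    occupancy[
        df["particle_id"].map(pidx).to_numpy(),
        df["step_index"].to_numpy(),
    ] = df["cell_id"].map(code).to_numpy()
    return ParticleTrackSet(
        cell_ids=cell_ids, occupancy=occupancy, step_duration=step_duration
    )


def write_particle_tracks(tracks: ParticleTrackSet, dest: Union[str, Path]) -> None:
    """Write a track set as a dense CSV (particle_id, step_index, cell_id)."""
    n_p, n_s = tracks.occupancy.shape
    labels = np.array(tracks.cell_ids + [OUTSIDE], dtype=object)
    pd.DataFrame(
        {
            "particle_id": np.repeat(np.arange(n_p), n_s),
            "step_index": np.tile(np.arange(n_s), n_p),
            "cell_id": labels[tracks.occupancy.ravel()],
        }
    ).to_csv(dest, index=False)


# ----------------------------------------------------------- environment IO


def read_cell_environment(source: Union[str, Path]) -> CellEnvironmentSeries:
    """Read an environment table (CSV: cell_id, step_index, temperature_c,
    salinity_ppt [, do_mg_l, tss_mg_l])."""
    df = pd.read_csv(source, dtype={"cell_id": str})
    required = ["cell_id", "step_index", "temperature_c", "salinity_ppt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrackFormatError(f"environment table missing columns {missing}")
    if df.duplicated(["cell_id", "step_index"]).any():
        raise TrackFormatError("duplicate (cell_id, step_index) rows")
    cell_ids = sorted(df["cell_id"].unique())
    steps = np.sort(df["step_index"].unique())
    n_steps = len(steps)
    if not np.array_equal(steps, np.arange(n_steps)):
        raise TrackFormatError("environment step indices must be contiguous from 0")
    if len(df) != len(cell_ids) * n_steps:
        raise TrackFormatError("environment table is not dense over cells × steps")

    cidx = {c: i for i, c in enumerate(cell_ids)}
    rows = df["cell_id"].map(cidx).to_numpy()
    cols = df["step_index"].to_numpy()

    def dense(col: str) -> np.ndarray:
        out = np.empty((len(cell_ids), n_steps), dtype=float)
        out[rows, cols] = df[col].to_numpy(dtype=float)
        return out

    return CellEnvironmentSeries(
        cell_ids=cell_ids,
        temperature=dense("temperature_c"),
        salinity=dense("salinity_ppt"),
        dissolved_oxygen=dense("do_mg_l") if "do_mg_l" in df.columns else None,
        seston=dense("tss_mg_l") if "tss_mg_l" in df.columns else None,
    )


def write_cell_environment(
    env: CellEnvironmentSeries, dest: Union[str, Path]
) -> None:
    """Write an environment series as a long CSV."""
    n_c, n_s = env.temperature.shape
    data = {
        "cell_id": np.repeat(np.array(env.cell_ids, dtype=object), n_s),
        "step_index": np.tile(np.arange(n_s), n_c),
        "temperature_c": env.temperature.ravel(),
        "salinity_ppt": env.salinity.ravel(),
    }
    if env.dissolved_oxygen is not None:
        data["do_mg_l"] = env.dissolved_oxygen.ravel()
    if env.seston is not None:
        data["tss_mg_l"] = env.seston.ravel()
    pd.DataFrame(data).to_csv(dest, index=False)


# -------------------------------------------------------------- geometry IO


def read_geometry(source: Union[str, Path]) -> list[CellGeometry]:
    """Read cell geometry (CSV: cell_id, surface_area_m2, volume_m3)."""
    df = pd.read_csv(source, dtype={"cell_id": str})
    required = ["cell_id", "surface_area_m2", "volume_m3"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrackFormatError(f"geometry table missing columns {missing}")
    if df["cell_id"].duplicated().any():
        raise TrackFormatError("duplicate cell_id rows in geometry table")
    return [
        CellGeometry(str(r.cell_id), float(r.surface_area_m2), float(r.volume_m3))
        for r in df.itertuples()
    ]


def write_geometry(geometry: Sequence[CellGeometry], dest: Union[str, Path]) -> None:
    """Write cell geometry as CSV."""
    pd.DataFrame(
        {
            "cell_id": [g.cell_id for g in geometry],
            "surface_area_m2": [g.surface_area for g in geometry],
            "volume_m3": [g.volume for g in geometry],
        }
    ).to_csv(dest, index=False)


# -------------------------------------------------------------- validation


def validate_domain(
    tracks: ParticleTrackSet,
    geometry: Sequence[CellGeometry],
    env: CellEnvironmentSeries,
) -> ValidationReport:
    """Cross-validate tracks against geometry and environment coverage.

    An empty report means: every cell any particle visits has geometry and
    a complete environment series covering all track steps.
    """
    report = ValidationReport()
    geom_ids = {g.cell_id for g in geometry}
    env_ids = set(env.cell_ids)
    referenced = tracks.referenced_cell_ids()

    for cell in sorted(referenced - geom_ids):
        report.findings.append(f"unknown cell: {cell} referenced by tracks has no geometry")
    for cell in sorted(referenced - env_ids):
        report.findings.append(f"coverage gap: {cell} referenced by tracks has no environment series")
    if env.n_steps < tracks.n_steps:
        report.findings.append(
            f"coverage gap: environment has {env.n_steps} steps but tracks have {tracks.n_steps}"
        )
    return report
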