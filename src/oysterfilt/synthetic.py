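"""Seeded synthetic estuaries: geometry, suitability, environment, particles.

The filtration model consumes four things a hydrodynamic + GIS toolchain
normally supplies: cell geometry, per-cell temperature/salinity series,
habitat-suitability areas, and hourly Lagrangian particle tracks.  This
module fabricates all four with the statistical structure the model
assumes — a rectangular grid with a river end and an ocean end, a monotone
salinity gradient oscillating with a ~12.4-h tide, temperatures near the
filtration optimum for a spring run, suitability concentrated in shallow
cells, and particles following a biased random walk (tidal advection along
the estuary axis plus isotropic dispersal).

It makes no claim to hydrodynamic realism: there is no momentum, no
stratification, no wind.  Its job is to exercise every downstream module
deterministically.  All randomness flows from the single config seed via
numpy SeedSequence spawning, so identical configs give bit-identical
fixtures.

The default configuration is a 30×12 grid of 600-m cells,
2–8 m deep, with 2000 particles over 336 hourly steps and salinity running
5→36 ppt from river to ocean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .bioenergetics import AbioticState
from .habitat import SuitabilityCell
from .transport import (
    CellEnvironmentSeries,
    CellGeometry,
    ParticleTrackSet,
)

__all__ = ["EstuaryConfig", "SyntheticEstuary", "generate_estuary", "simulate_particles", "generate_fixture"]

#: Principal lunar semidiurnal (M2) tidal period, hours.
TIDAL_PERIOD_H = 12.4


@dataclass(frozen=True)
class EstuaryConfig:
    """Configuration of a synthetic estuary.

    The x axis runs from the river end (x = 0, fresh) to the ocean end
    (x = n_cells_x − 1, salty); particles crossing the ocean edge leave
    the domain (OUTSIDE) and may re-enter on the flood phase.
    ``tidal_amplitude`` is the peak probability of a one-cell advective
    hop per step; ``dispersal_scale`` the per-step probability of a random
    one-cell hop.
    """

    seed: int
    n_cells_x: int = 30
    n_cells_y: int = 12
    cell_side: float = 600.0
    depth_range: tuple[float, float] = (2.0, 8.0)
    tidal_amplitude: float = 0.6
    dispersal_scale: float = 0.5
    salinity_range: tuple[float, float] = (5.0, 36.0)
    temperature_mean: float = 27.0
    temperature_amplitude: float = 2.0
    n_particles: int = 2000
    n_steps: int = 336
    reentry_probability: float = 0.25
    include_optional_fields: bool = False
    closed_domain: bool = False  # True: ocean edge reflects too (no OUTSIDE)

    def __post_init__(self) -> None:
        if self.n_cells_x < 1 or self.n_cells_y < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.cell_side <= 0:
            raise ValueError("cell_side must be > 0 m")
        if not (0 < self.depth_range[0] <= self.depth_range[1]):
            raise ValueError("depth_range must be 0 < min <= max")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        lo, hi = self.salinity_range
        if not (0 <= lo <= hi <= 40):
            raise ValueError("salinity_range must lie within [0, 40] ppt")
        for name in ("tidal_amplitude", "dispersal_scale", "reentry_probability"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return self.n_cells_x * self.n_cells_y


@dataclass
class SyntheticEstuary:
    """A generated estuary: geometry, suitability, environment, and config."""

    config: EstuaryConfig
    geometry: list[CellGeometry]
    suitability: list[SuitabilityCell]
    environment: CellEnvironmentSeries
    depths: np.ndarray  # (n_cells_x, n_cells_y)


def _cell_id(ix: int, iy: int) -> str:
    return f"c{ix:03d}_{iy:03d}"


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Independent, reproducible generators for each stochastic component."""
    names = ["depth", "suitability", "temperature", "particles", "optional"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _tide(step: np.ndarray | int) -> np.ndarray | float:
    """Tidal phase: positive on ebb (seaward), negative on flood."""
    return np.sin(2 * np.pi * np.asarray(step, dtype=float) / TIDAL_PERIOD_H)


def generate_estuary(config: EstuaryConfig) -> SyntheticEstuary:
    """Generate geometry, suitability and environment for one estuary.

    Cell volumes are surface area × depth, with depths drawn uniformly
    from ``depth_range``.  Salinity rises monotonically from river to
    ocean end and the whole gradient slides with the tide.  Temperature
    follows a diel cycle around ``temperature_mean`` with a fixed per-cell
    offset.  Suitability areas go preferentially to shallow cells, and
    mapped historical-reef areas (for the restorable-proportion fit) are
    drawn around true coverage proportions of 0.177 (high) and 0.110
    (medium), zeroed in a fraction of cells to mimic reef absence.
    """
    rngs = _streams(config.seed)
    nx, ny = config.n_cells_x, config.n_cells_y
    area = config.cell_side**2
    depths = rngs["depth"].uniform(*config.depth_range, size=(nx, ny))

    geometry = [
        CellGeometry(_cell_id(ix, iy), area, area * depths[ix, iy])
        for ix in range(nx)
        for iy in range(ny)
    ]

    # suitability: shallow cells get larger suitable fractions
    rng = rngs["suitability"]
    d_lo, d_hi = config.depth_range
    shallowness = (d_hi - depths) / max(d_hi - d_lo, 1e-12)  # 1 = shallowest
    suitability = []
    for ix in range(nx):
        for iy in range(ny):
            w = shallowness[ix, iy]
            has_habitat = rng.random() < 0.2 + 0.5 * w
            if has_habitat:
                frac_high = 0.25 * w * rng.random()
                frac_med = 0.35 * w * rng.random()
            else:
                frac_high = frac_med = 0.0
            a_high, a_med = frac_high * area, frac_med * area
            # historical mapping: noisy proportional coverage, absent in
            # ~35% of otherwise suitable cells
            if has_habitat and rng.random() > 0.35:
                noise = rng.lognormal(mean=0.0, sigma=0.3, size=2)
                m_high = min(0.177 * a_high * noise[0], a_high)
                m_med = min(0.110 * a_med * noise[1], a_med)
            else:
                m_high = m_med = None
            suitability.append(
                SuitabilityCell(
                    cell_id=_cell_id(ix, iy),
                    area_high=a_high,
                    area_medium=a_med,
                    mapped_oyster_area_high=m_high,
                    mapped_oyster_area_medium=m_med,
                )
            )

    # environment: monotone salinity gradient sliding with the tide;
    # diel temperature cycle with a fixed per-cell offset
    steps = np.arange(config.n_steps)
    s_lo, s_hi = config.salinity_range
    xfrac = np.repeat(np.arange(nx), ny) / max(nx - 1, 1)  # cell-id order
    shift = 0.05 * config.tidal_amplitude * _tide(steps)
    xeff = np.clip(xfrac[:, None] + shift[None, :], 0.0, 1.0)
    salinity = s_lo + (s_hi - s_lo) * xeff

    cell_offset = rngs["temperature"].uniform(-0.5, 0.5, size=config.n_cells)
    temperature = (
        config.temperature_mean
        + config.temperature_amplitude * np.sin(2 * np.pi * steps / 24.0)[None, :]
        + cell_offset[:, None]
    )

    do = tss = None
    if config.include_optional_fields:
        rng_o = rngs["optional"]
        do = np.clip(
            rng_o.normal(6.0, 1.0, size=(config.n_cells, config.n_steps)), 0, None
        )
        tss = np.clip(
            rng_o.normal(12.0, 5.0, size=(config.n_cells, config.n_steps)), 0, None
        )

    env = CellEnvironmentSeries(
        cell_ids=[_cell_id(ix, iy) for ix in range(nx) for iy in range(ny)],
        temperature=temperature,
        salinity=salinity,
        dissolved_oxygen=do,
        seston=tss,
    )
    return SyntheticEstuary(
        config=config,
        geometry=geometry,
        suitability=suitability,
        environment=env,
        depths=depths,
    )


def simulate_particles(estuary: SyntheticEstuary) -> ParticleTrackSet:
    """Biased-random-walk particle tracks over the estuary grid.

    Each step, every in-domain particle makes an advective hop of ±1 cell
    along the estuary axis with probability tidal_amplitude·|sin(2πt/12.4)|
    (seaward on ebb, riverward on flood), plus an isotropic one-cell
    dispersal hop with probability dispersal_scale.  Moves off the river
    end or the lateral banks are rejected (the particle stays), which
    keeps the pure-dispersal walk doubly stochastic and hence uniform at
    stationarity.  Crossing the ocean edge sends the particle OUTSIDE;
    while outside it re-enters at a random ocean-edge cell with
    probability reentry_probability on flood steps only.
    """
    config = estuary.config
    rng = _streams(config.seed)["particles"]
    nx, ny = config.n_cells_x, config.n_cells_y
    n_p, n_s = config.n_particles, config.n_steps

    x = rng.integers(0, nx, size=n_p)
    y = rng.integers(0, ny, size=n_p)
    outside = np.zeros(n_p, dtype=bool)

    occupancy = np.empty((n_p, n_s), dtype=np.int32)
    for t in range(n_s):
        phase = float(_tide(t))
        # re-entry of OUTSIDE particles on flood
        if outside.any() and phase < 0 and not config.closed_domain:
            back = outside & (rng.random(n_p) < config.reentry_probability)
            if back.any():
                x[back] = nx - 1
                y[back] = rng.integers(0, ny, size=int(back.sum()))
                outside[back] = False

        inside = ~outside
        # tidal advection along x: +1 on ebb (toward ocean), -1 on flood
        p_adv = config.tidal_amplitude * abs(phase)
        adv = (rng.random(n_p) < p_adv) & inside
        dx = np.where(adv, int(np.sign(phase)) if phase != 0 else 0, 0)

        # isotropic dispersal: one of 4 neighbours with prob dispersal_scale
        disp = (rng.random(n_p) < config.dispersal_scale) & inside
        direction = rng.integers(0, 4, size=n_p)
        ddx = np.where(disp, np.choose(direction, [1, -1, 0, 0]), 0)
        ddy = np.where(disp, np.choose(direction, [0, 0, 1, -1]), 0)

        nx_pos = x + dx + ddx
        ny_pos = y + ddy
        # reject moves over the river end or the banks (particle stays)
        bad_y = (ny_pos < 0) | (ny_pos >= ny)
        ny_pos = np.where(bad_y, y, ny_pos)
        bad_x = nx_pos < 0
        if config.closed_domain:
            bad_x |= nx_pos >= nx
        nx_pos = np.where(bad_x, x, nx_pos)

        leaving = (nx_pos >= nx) & inside
        if leaving.any():
            outside |= leaving
        keep = inside & ~leaving
        x = np.where(keep, nx_pos, x)
        y = np.where(keep, ny_pos, y)

        occupancy[:, t] = np.where(outside, -1, x * ny + y)

    cell_ids = [_cell_id(ix, iy) for ix in range(nx) for iy in range(ny)]
    return ParticleTrackSet(cell_ids=cell_ids, occupancy=occupancy, step_duration=1.0)


def generate_fixture(
    config: EstuaryConfig,
) -> tuple[SyntheticEstuary, ParticleTrackSet]:
    """Generate an estuary and its particle tracks in one call."""
    estuary = generate_estuary(config)
    return estuary, simulate_particles(estuary)
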