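"""Shared fixtures: hand-built micro-domains and small synthetic estuaries."""

from __future__ import annotations

import numpy as np
import pytest

from oysterfilt import (
    AbioticState,
    CellEnvironmentSeries,
    CellGeometry,
    DemographicScenario,
    EstuaryConfig,
    ParticleTrackSet,
    RestorationFootprint,
    SizeClassSpec,
    generate_fixture,
)
from oysterfilt.bioenergetics import base_areal_rate
from oysterfilt.transport import OUTSIDE


@pytest.fixture
def unit_scenario() -> DemographicScenario:
    """One size class of density 1 m^-2 whose mean oyster weighs 1 g DTW,
    so the optimum areal rate is ~8.02 L/h/m^2."""
    L = 10.0 ** (4.0 / 2.1)  # dtw_from_shell_height(L) == 1 g
    return DemographicScenario(
        classes=(SizeClassSpec("unit", L, 1.0),), name="unit"
    )


@pytest.fixture
def table_scenario() -> DemographicScenario:
    """The spat/seed/market successful-restoration scenario."""
    return DemographicScenario(
        classes=(
            SizeClassSpec("spat", 16.0, 61.0),
            SizeClassSpec("seed", 56.0, 125.0),
            SizeClassSpec("market", 98.0, 34.0),
        ),
        name="successful",
    )


def build_domain(
    occupancy_ids: list[list[str]],
    volumes: dict[str, float],
    reef_areas: dict[str, float],
    temperature: float = 27.0,
    salinity: float = 36.0,
):
    """Assemble a manual (tracks, env, geometry, footprints) micro-domain.

    ``occupancy_ids`` is one list of cell-id strings (or OUTSIDE) per
    particle; abiotic conditions are constant everywhere.
    """
    n_steps = len(occupancy_ids[0])
    cell_ids = sorted(volumes)
    code = {c: i for i, c in enumerate(cell_ids)}
    code[OUTSIDE] = -1
    occ = np.array([[code[c] for c in row] for row in occupancy_ids], dtype=np.int32)
    tracks = ParticleTrackSet(cell_ids=cell_ids, occupancy=occ, step_duration=1.0)
    env = CellEnvironmentSeries(
        cell_ids=cell_ids,
        temperature=np.full((len(cell_ids), n_steps), temperature),
        salinity=np.full((len(cell_ids), n_steps), salinity),
    )
    geometry = [CellGeometry(c, max(volumes[c], 1.0), volumes[c]) for c in cell_ids]
    footprints = [
        RestorationFootprint(c, reef_areas.get(c, 0.0)) for c in cell_ids
    ]
    return tracks, env, geometry, footprints


def reef_area_for_rate(
    F: float, volume: float, scenario: DemographicScenario
) -> float:
    """Reef area (m^2) giving rate constant F (1/h) in a cell of `volume`
    at optimal abiotic conditions (modifier product 1)."""
    return F * 1000.0 * volume / base_areal_rate(scenario)


@pytest.fixture
def small_estuary():
    """A small seeded synthetic estuary with its particle tracks."""
    cfg = EstuaryConfig(
        seed=11, n_cells_x=12, n_cells_y=5, n_particles=120, n_steps=48
    )
    return generate_fixture(cfg)
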