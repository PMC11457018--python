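"""Load-decay engine: rate constants, step bookkeeping, exposures, conservation."""

import math

import numpy as np
import pytest

from oysterfilt import (
    AbioticState,
    CellGeometry,
    DomainValidationError,
    EstuaryConfig,
    FiltrationRunConfig,
    RestorationFootprint,
    cell_rate_constant,
    exposure_matrix,
    generate_fixture,
    project_restorable_area,
    run_filtration,
    successful_restoration_scenario,
)
from conftest import build_domain, reef_area_for_rate

OPTIMAL = AbioticState(27.0, 36.0)


class TestRateConstant:
    def test_zero_footprint_gives_zero(self, unit_scenario):
        F = cell_rate_constant(
            RestorationFootprint("a", 0.0),
            CellGeometry("a", 100.0, 1000.0),
            OPTIMAL,
            unit_scenario,
        )
        assert F == 0.0

    def test_unit_conversion(self, table_scenario):
        # areal rate 1062.293... L/h/m2 at optimum; 1000 m2 reef in 10000 m3
        F = cell_rate_constant(
            RestorationFootprint("a", 1000.0),
            CellGeometry("a", 1000.0, 10_000.0),
            OPTIMAL,
            table_scenario,
        )
        assert F == pytest.approx(1062.29314783468 * 1000.0 / 1000.0 / 10_000.0,
                                  rel=1e-11)

    def test_inverse_in_volume(self, unit_scenario):
        args = (RestorationFootprint("a", 500.0), OPTIMAL, unit_scenario)
        F1 = cell_rate_constant(args[0], CellGeometry("a", 1.0, 2000.0), *args[1:])
        F2 = cell_rate_constant(args[0], CellGeometry("a", 1.0, 4000.0), *args[1:])
        assert F1 == pytest.approx(2 * F2, rel=1e-12)


class TestRunFiltration:
    def test_no_footprints_means_no_filtration(self, unit_scenario):
        tracks, env, geom, _ = build_domain(
            [["a", "a", "a"]], volumes={"a": 1000.0}, reef_areas={}
        )
        cfg = FiltrationRunConfig(scenario=unit_scenario, footprints=[])
        res = run_filtration(cfg, tracks, env, geom)
        assert np.all(res.final_loads == 1.0)
        assert np.all(res.curve.fraction_cleared == 0.0)
        assert res.summaries == []

    def test_halving_per_step(self, unit_scenario):
        """Constant F·dt = ln 2 halves the load each step."""
        area = reef_area_for_rate(math.log(2.0), 1000.0, unit_scenario)
        tracks, env, geom, foot = build_domain(
            [["a", "a", "a"]], volumes={"a": 1000.0}, reef_areas={"a": area}
        )
        cfg = FiltrationRunConfig(scenario=unit_scenario, footprints=foot)
        res = run_filtration(cfg, tracks, env, geom)
        assert res.final_loads[0] == pytest.approx(1 / 8, rel=1e-12)
        assert res.summaries[0].contribution == pytest.approx(7 / 8, rel=1e-12)
        np.testing.assert_allclose(
            res.curve.fraction_cleared, [0.5, 0.75, 0.875], rtol=1e-12
        )

    def test_two_cell_sequential_attribution(self, unit_scenario):
        """Visiting two cells: removal attribution is order-dependent but
        the final load depends only on total exposure."""
        vols = {"a": 1000.0, "b": 1000.0}
        areas = {
            "a": reef_area_for_rate(0.2, 1000.0, unit_scenario),
            "b": reef_area_for_rate(0.5, 1000.0, unit_scenario),
        }
        tracks, env, geom, foot = build_domain(
            [["a", "b"]], volumes=vols, reef_areas=areas
        )
        cfg = FiltrationRunConfig(scenario=unit_scenario, footprints=foot)
        res = run_filtration(cfg, tracks, env, geom)
        # hand-computed with mpmath: exp(-0.7), 1-exp(-0.2), exp(-0.2)(1-exp(-0.5))
        assert res.final_loads[0] == pytest.approx(0.496585303791410, rel=1e-12)
        by_id = {s.cell_id: s.contribution for s in res.summaries}
        assert by_id["a"] == pytest.approx(0.181269246922018, rel=1e-12)
        assert by_id["b"] == pytest.approx(0.322145449286572, rel=1e-12)

    def test_outside_leaves_load_unchanged(self, unit_scenario):
        area = reef_area_for_rate(1.0, 1000.0, unit_scenario)
        tracks, env, geom, foot = build_domain(
            [["a", "OUTSIDE", "a"]], volumes={"a": 1000.0}, reef_areas={"a": area}
        )
        cfg = FiltrationRunConfig(scenario=unit_scenario, footprints=foot)
        res = run_filtration(cfg, tracks, env, geom)
        # two active steps only
        assert res.final_loads[0] == pytest.approx(math.exp(-2.0), rel=1e-12)
        assert res.curve.fraction_cleared[1] == res.curve.fraction_cleared[0]

    def test_closed_form_single_cell_curve(self, unit_scenario):
        """With one perfectly mixed cell and constant F the cumulative
        curve is exactly 1 - exp(-F t)."""
        F = 0.03
        area = reef_area_for_rate(F, 5000.0, unit_scenario)
        n_steps = 100
        tracks, env, geom, foot = build_domain(
            [["a"] * n_steps] * 7, volumes={"a": 5000.0}, reef_areas={"a": area}
        )
        cfg = FiltrationRunConfig(scenario=unit_scenario, footprints=foot)
        res = run_filtration(cfg, tracks, env, geom)
        t = np.arange(1, n_steps + 1, dtype=float)
        np.testing.assert_allclose(
            res.curve.fraction_cleared, 1.0 - np.exp(-F * t), atol=1e-9
        )

    def test_validation_gate_before_computation(self, unit_scenario, small_estuary):
        estuary, tracks = small_estuary
        cfg = FiltrationRunConfig(scenario=unit_scenario, footprints=[])
        geometry = estuary.geometry[: len(estuary.geometry) // 2]
        with pytest.raises(DomainValidationError):
            run_filtration(cfg, tracks, estuary.environment, geometry)

    def test_mean_and_areal_rates_consistent(self, small_estuary):
        estuary, tracks = small_estuary
        scen = successful_restoration_scenario()
        foot = project_restorable_area(estuary.suitability, 0.177, 0.110)
        cfg = FiltrationRunConfig(scenario=scen, footprints=foot)
        res = run_filtration(cfg, tracks, estuary.environment, estuary.geometry)
        assert res.summaries
        for s in res.summaries:
            assert s.areal_rate == pytest.approx(
                s.mean_volumetric_rate * 1000.0 / s.reef_area, rel=1e-12
            )
            assert s.contribution >= 0.0


class TestConservation:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_contributions_plus_loads_conserve_particles(self, seed):
        cfg_e = EstuaryConfig(
            seed=seed, n_cells_x=10, n_cells_y=4, n_particles=80, n_steps=36
        )
        estuary, tracks = generate_fixture(cfg_e)
        scen = successful_restoration_scenario()
        foot = project_restorable_area(estuary.suitability, 0.177, 0.110)
        cfg = FiltrationRunConfig(scenario=scen, footprints=foot)
        res = run_filtration(cfg, tracks, estuary.environment, estuary.geometry)
        total = sum(s.contribution for s in res.summaries) + res.final_loads.sum()
        assert total == pytest.approx(res.n_particles, abs=1e-9)

    def test_curve_monotone_and_bounded(self, small_estuary):
        estuary, tracks = small_estuary
        scen = successful_restoration_scenario()
        foot = project_restorable_area(estuary.suitability, 0.177, 0.110)
        cfg = FiltrationRunConfig(scenario=scen, footprints=foot)
        res = run_filtration(cfg, tracks, estuary.environment, estuary.geometry)
        frac = res.curve.fraction_cleared
        assert np.all(np.diff(frac) >= -1e-15)
        assert np.all((frac >= 0) & (frac <= 1))
        # bounded by the fraction of particles that ever occupy a restored cell
        restored = {s.cell_id for s in res.summaries}
        codes = {
            i for i, c in enumerate(tracks.cell_ids) if c in restored
        }
        ever = np.isin(tracks.occupancy, list(codes)).any(axis=1)
        assert frac[-1] <= ever.mean() + 1e-12


class TestExposureMatrix:
    def test_single_cell_exposure_is_rate_times_residence(self, unit_scenario):
        area = reef_area_for_rate(0.25, 1000.0, unit_scenario)
        tracks, env, geom, foot = build_domain(
            [["a", "a", "a", "a"]], volumes={"a": 1000.0}, reef_areas={"a": area}
        )
        E = exposure_matrix(tracks, env, geom, unit_scenario, foot)
        assert E.exposures[0, 0] == pytest.approx(0.25 * 4, rel=1e-12)

    def test_matches_step_by_step_loads(self, small_estuary):
        estuary, tracks = small_estuary
        scen = successful_restoration_scenario()
        foot = project_restorable_area(estuary.suitability, 0.177, 0.110)
        cfg = FiltrationRunConfig(scenario=scen, footprints=foot)
        res = run_filtration(cfg, tracks, estuary.environment, estuary.geometry)
        E = exposure_matrix(
            tracks, estuary.environment, estuary.geometry, scen, foot
        )
        np.testing.assert_allclose(E.final_loads(), res.final_loads, atol=1e-10)

    def test_visit_order_does_not_change_final_load(self, unit_scenario):
        vols = {"a": 1000.0, "b": 2000.0}
        areas = {
            "a": reef_area_for_rate(0.3, 1000.0, unit_scenario),
            "b": reef_area_for_rate(0.1, 2000.0, unit_scenario),
        }
        t1, env1, geom, foot = build_domain(
            [["a", "a", "b"]], volumes=vols, reef_areas=areas
        )
        t2, env2, _, _ = build_domain(
            [["b", "a", "a"]], volumes=vols, reef_areas=areas
        )
        E1 = exposure_matrix(t1, env1, geom, unit_scenario, foot)
        E2 = exposure_matrix(t2, env2, geom, unit_scenario, foot)
        assert E1.final_loads()[0] == pytest.approx(E2.final_loads()[0], rel=1e-12)

    def test_monotone_in_footprint_area(self, small_estuary):
        """Enlarging any footprint never decreases total filtration."""
        estuary, tracks = small_estuary
        scen = successful_restoration_scenario()
        foot = project_restorable_area(estuary.suitability, 0.1, 0.05)
        E = exposure_matrix(
            tracks, estuary.environment, estuary.geometry, scen, foot
        )
        base_total = E.total_filtration()
        bigger = project_restorable_area(estuary.suitability, 0.15, 0.05)
        E2 = exposure_matrix(
            tracks, estuary.environment, estuary.geometry, scen, bigger
        )
        assert E2.total_filtration() >= base_total - 1e-12
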