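import math

import numpy as np
import pytest

from arcqa.geometry import BeamGeometry, GeometryConfigError
from arcqa.formats import PlanSpec
from arcqa.synthetic import (
    GridSpec,
    MediumConfig,
    ResponseModel,
    beam_dose_at_points,
    generate_scenario,
    make_correction_tables,
    plan_sum,
    simulate_beam_dose,
    simulate_measurement,
    simulate_plan,
    split_plan,
)


def _beam(angle=0.0, time=2.0, head=1, aperture=(10.0, 10.0)):
    return BeamGeometry(head_id=head, gantry_angle=angle,
                        beam_on_time=time, aperture=aperture)


class TestBeamDose:
    def test_zero_beam_on_time_gives_zero_grid(self, grid_spec):
        g = simulate_beam_dose(_beam(time=0.0), grid_spec)
        assert np.all(g.values == 0.0)

    def test_opposed_beams_are_mirror_images(self, grid_spec):
        g0 = simulate_beam_dose(_beam(0.0), grid_spec)
        g180 = simulate_beam_dose(_beam(180.0), grid_spec)
        # gantry 0 enters from +y, gantry 180 from -y: reflect the y axis
        assert np.max(np.abs(g0.values - g180.values[:, ::-1, :])) < 1e-9

    def test_central_axis_matches_scalar_oracle(self):
        # independent per-point formula: inverse square x attenuation x
        # on-axis aperture transmission, entry at the cylinder surface
        med = MediumConfig()
        beam = _beam(0.0, time=2.0)
        sad = beam.source_axis_distance
        ys = np.array([10.0, 5.0, 0.0, -5.0])
        pts = np.column_stack([np.zeros_like(ys), ys, np.zeros_like(ys)])
        got = beam_dose_at_points(beam, pts, med)
        s2 = med.penumbra_sigma * math.sqrt(2.0)
        t_on_axis = math.erf(beam.aperture[0] / 2 / s2) * math.erf(
            beam.aperture[1] / 2 / s2)
        for y, dose in zip(ys, got):
            dist = sad - y
            depth = med.outer_radius - y  # on axis: straight through the shell
            oracle = (beam.output_rate * beam.beam_on_time / 60.0
                      * (sad / dist) ** 2
                      * math.exp(-med.mu_eff_water * med.density * depth)
                      * t_on_axis)
            assert dose == pytest.approx(oracle, rel=1e-9)

    def test_dose_increases_with_beam_on_time(self, grid_spec):
        g1 = simulate_beam_dose(_beam(time=1.0), grid_spec)
        g2 = simulate_beam_dose(_beam(time=2.5), grid_spec)
        nz = g1.values > 0
        assert np.all(g2.values[nz] > g1.values[nz])

    def test_grid_missing_isocenter_rejected(self):
        spec = GridSpec(origin=(5.0, 5.0, 5.0), spacing=(1, 1, 1), shape=(3, 3, 3))
        with pytest.raises(GeometryConfigError):
            simulate_beam_dose(_beam(), spec)

    def test_tps_density_override_changes_attenuation(self, grid_spec):
        med = MediumConfig(tps_density=1.125)
        truth = simulate_beam_dose(_beam(), grid_spec, med)
        tps = simulate_beam_dose(_beam(), grid_spec, med, tps=True)
        # lighter TPS medium attenuates less: higher dose beyond the surface
        assert tps.values[tps.values > 0].max() > 0
        assert not np.allclose(tps.values, truth.values)


class TestSimulatePlan:
    def test_per_beam_grids_and_exact_sum(self, three_beam_plan, grid_spec):
        grids = simulate_plan(three_beam_plan, grid_spec)
        assert len(grids) == 3
        total = plan_sum(grids)
        assert np.array_equal(
            total.values, grids[0].values + grids[1].values + grids[2].values
        )

    def test_beam_order_does_not_change_sum(self, three_beam_plan, grid_spec):
        grids = simulate_plan(three_beam_plan, grid_spec)
        reordered = PlanSpec("r", list(reversed(three_beam_plan.beams)))
        grids_r = simulate_plan(reordered, grid_spec)
        assert np.allclose(plan_sum(grids).values, plan_sum(grids_r).values)

    def test_zero_time_beam_contributes_zero(self, grid_spec):
        plan = PlanSpec("p", [_beam(0.0, time=2.0, head=1),
                              _beam(120.0, time=0.0, head=2)])
        grids = simulate_plan(plan, grid_spec)
        assert np.all(grids[1].values == 0.0)


class TestSimulateMeasurement:
    def test_identity_response_reproduces_plan_interpolation(
            self, geometry, three_beam_plan, grid_spec):
        grids = simulate_plan(three_beam_plan, grid_spec)
        model = ResponseModel.identity(geometry.n_diodes)
        _, mset = simulate_measurement(three_beam_plan, grids, geometry, model)
        expected = plan_sum(grids).interpolate(geometry.positions())
        nz = expected > 1e-12
        assert np.max(np.abs(mset.totals[nz] - expected[nz]) / expected[nz]) < 1e-9

    def test_pure_bias_shifts_median_percent_difference_exactly(
            self, geometry, three_beam_plan, grid_spec):
        grids = simulate_plan(three_beam_plan, grid_spec)
        model = ResponseModel.identity(geometry.n_diodes)
        model.magnetic_bias = 0.05
        _, mset = simulate_measurement(three_beam_plan, grids, geometry, model)
        expected = plan_sum(grids).interpolate(geometry.positions())
        nz = expected > 0.1 * expected.max()
        pct = 100.0 * (mset.totals[nz] - expected[nz]) / expected[nz]
        assert np.median(pct) == pytest.approx(5.0, abs=1e-9)

    def test_seed_contract(self, geometry, single_beam_plan, grid_spec):
        grids = simulate_plan(single_beam_plan, grid_spec)
        model = ResponseModel.default(geometry.n_diodes, seed=1)
        _, a = simulate_measurement(single_beam_plan, grids, geometry, model, seed=7)
        _, b = simulate_measurement(single_beam_plan, grids, geometry, model, seed=7)
        _, c = simulate_measurement(single_beam_plan, grids, geometry, model, seed=8)
        assert np.array_equal(a.totals, b.totals)
        assert not np.array_equal(a.totals, c.totals)

    def test_frame_totals_invariant(self, geometry, three_beam_plan, grid_spec):
        grids = simulate_plan(three_beam_plan, grid_spec)
        model = ResponseModel.default(geometry.n_diodes, seed=2)
        series, mset = simulate_measurement(three_beam_plan, grids, geometry, model)
        assert mset.check_frame_totals()
        assert series.frames.min() >= 0

    def test_sequential_mode_keeps_one_beam_per_frame(
            self, geometry, three_beam_plan, grid_spec):
        grids = simulate_plan(three_beam_plan, grid_spec)
        model = ResponseModel.identity(geometry.n_diodes)
        series, mset = simulate_measurement(
            three_beam_plan, grids, geometry, model, simultaneous=False)
        assert all(len(s) == 1 for s in series.active_beams)
        expected = plan_sum(grids).interpolate(geometry.positions())
        nz = expected > 1e-12
        assert np.max(np.abs(mset.totals[nz] - expected[nz]) / expected[nz]) < 1e-9


class TestCorrectionTables:
    def test_identity_model_gives_unit_tables(self, geometry):
        t = make_correction_tables(ResponseModel.identity(geometry.n_diodes))
        assert np.all(t.c_ad == 1.0)
        assert np.all(t.c_id == 1.0)
        assert np.all(t.c_fs == 1.0)
        assert np.all(t.c_hf == 1.0)

    def test_tables_are_reciprocal_at_every_node(self, geometry):
        model = ResponseModel.default(geometry.n_diodes, seed=3)
        t = make_correction_tables(model)
        assert np.allclose(model.angular_curve(t.angle_nodes) * t.c_ad, 1.0)
        assert np.allclose(model.sensitivity * t.c_id, 1.0)
        assert np.allclose(model.field_size_curve(t.fs_nodes) * t.c_fs, 1.0)

    def test_known_over_response_maps_to_23_percent(self):
        from arcqa.corrections import max_correction_reduction
        model = ResponseModel.identity(10)
        model.angular_curve = lambda p: np.full_like(
            np.asarray(p, dtype=float), 1.23)
        t = make_correction_tables(model)
        r = max_correction_reduction(t, {"AD", "ID", "HF"})
        assert r == pytest.approx(23.0, abs=1e-9)

    def test_nonpositive_response_rejected(self):
        model = ResponseModel.identity(4)
        model.angular_curve = lambda p: np.cos(np.deg2rad(np.asarray(p)))
        with pytest.raises(ValueError):
            make_correction_tables(model)


class TestSplitPlan:
    def test_three_beam_plan_splits_into_three(self, three_beam_plan):
        parts = split_plan(three_beam_plan)
        assert len(parts) == 3
        assert all(len(p.beams) == 1 for p in parts)
        assert all(p.plan_id.startswith("triple#head") for p in parts)
        assert [p.beams[0] for p in parts] == three_beam_plan.beams

    def test_single_beam_plan_unchanged(self, single_beam_plan):
        assert split_plan(single_beam_plan) == [single_beam_plan]

    def test_split_measurements_sum_to_simultaneous(
            self, geometry, three_beam_plan, grid_spec):
        # noiseless response without any dose-rate term: frame-additive
        grids = simulate_plan(three_beam_plan, grid_spec)
        model = ResponseModel.default(geometry.n_diodes, seed=4, noise_sd=0.0)
        _, together = simulate_measurement(three_beam_plan, grids, geometry, model)
        summed = np.zeros(geometry.n_diodes)
        for part, grid in zip(split_plan(three_beam_plan), grids):
            _, m = simulate_measurement(part, [grid], geometry, model)
            summed += m.totals
        nz = together.totals > 1e-12
        assert np.max(
            np.abs(summed[nz] - together.totals[nz]) / together.totals[nz]
        ) < 1e-9


class TestScenario:
    def test_scenario_structure_and_determinism(self, geometry):
        a = generate_scenario(n_plans=2, seed=5, geometry=geometry)
        b = generate_scenario(n_plans=2, seed=5, geometry=geometry)
        assert len(a["plans"]) == len(a["grids"]) == len(a["measurements"]) == 2
        assert all(len(g) == 3 for g in a["grids"])
        for ma, mb in zip(a["measurements"], b["measurements"]):
            assert np.array_equal(ma.totals, mb.totals)
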