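import numpy as np
import pytest

from arcqa.corrections import (
    CorrectionTables,
    DoseFractionMatrix,
    TableEvaluationError,
    apply_framewise_corrections,
    apply_weighted_corrections,
    compute_dose_fractions,
    max_correction_reduction,
)
from arcqa.formats import DoseGrid
from arcqa.geometry import ArrayConfig, BeamGeometry, build_geometry
from arcqa.inclinometer import FrameAngleEstimate
from arcqa.measurement import ConsistencyError, DiodeMeasurementSet, FrameSeries
from arcqa.synthetic import (
    ResponseModel,
    make_correction_tables,
    simulate_measurement,
    simulate_plan,
)


def _unit_tables(n_diodes, angle_step=45.0):
    nodes = np.arange(0.0, 360.0, angle_step)
    return CorrectionTables(
        angle_nodes=nodes, c_ad=np.ones_like(nodes), c_id=np.ones(n_diodes),
        fs_nodes=np.array([1.0, 40.0]), c_fs=np.ones(2), c_hf=np.ones_like(nodes),
    )


def _tiny_geometry(n=1):
    return build_geometry(ArrayConfig(n_diodes=n, helix_turns=1))


class TestDoseFractions:
    def test_single_beam_fractions_are_one(self, geometry, single_beam_plan, grid_spec):
        grids = simulate_plan(single_beam_plan, grid_spec)
        F = compute_dose_fractions(grids, geometry)
        assert np.all(F.F[~F.flagged, 0] == 1.0)
        assert np.all(F.F[F.flagged] == 0.0)

    def test_identical_grids_split_evenly(self, geometry, single_beam_plan, grid_spec):
        grids = simulate_plan(single_beam_plan, grid_spec)
        F = compute_dose_fractions([grids[0], grids[0]], geometry)
        assert np.allclose(F.F[~F.flagged], 0.5)

    def test_rows_sum_to_one_and_match_scalar_oracle(
            self, geometry, three_beam_plan, grid_spec):
        from scipy.interpolate import RegularGridInterpolator
        grids = simulate_plan(three_beam_plan, grid_spec)
        F = compute_dose_fractions(grids, geometry)
        assert np.max(np.abs(F.F[~F.flagged].sum(axis=1) - 1.0)) < 1e-9
        # independent per-point interpolation for a handful of diodes
        pos = geometry.positions()
        interps = [
            RegularGridInterpolator(g.axis_coords(), g.values) for g in grids
        ]
        for i in np.flatnonzero(~F.flagged)[::211]:
            d = np.array([float(itp(pos[i])[0]) for itp in interps])
            assert np.allclose(F.F[i], d / d.sum(), atol=1e-9)

    def test_detector_outside_all_grids_rejected(self, geometry):
        tiny = DoseGrid(np.ones((2, 2, 2)), (100.0, 100.0, 100.0), (1, 1, 1))
        with pytest.raises(ConsistencyError):
            compute_dose_fractions([tiny], geometry)

    def test_invalid_fraction_matrix_rejected(self):
        with pytest.raises(ConsistencyError):
            DoseFractionMatrix(F=np.array([[0.6, 0.6]]), flagged=np.array([False]))


class TestWeightedCorrections:
    def test_unit_tables_are_identity(self, geometry, three_beam_plan, grid_spec):
        grids = simulate_plan(three_beam_plan, grid_spec)
        model = ResponseModel.default(geometry.n_diodes, seed=1)
        _, mset = simulate_measurement(three_beam_plan, grids, geometry, model)
        F = compute_dose_fractions(grids, geometry)
        out = apply_weighted_corrections(
            mset, F, _unit_tables(geometry.n_diodes), three_beam_plan.beams, geometry)
        assert np.max(np.abs(out.totals - mset.totals)) <= 1e-12 * mset.totals.max()
        assert out.corrected and out.method == "weighted"

    def test_hand_worked_two_beam_example(self):
        # one diode at azimuth 0; beams at gantry 0 and 180 see factor
        # products 0.95 and 1.05; F = (0.7, 0.3):
        # 100 * (0.7*0.95 + 0.3*1.05) = 98.0
        geom = _tiny_geometry(1)
        nodes = np.arange(0.0, 360.0, 90.0)
        tables = CorrectionTables(
            angle_nodes=nodes, c_ad=np.array([0.95, 1.0, 1.05, 1.0]),
            c_id=np.ones(1), fs_nodes=np.array([1.0, 40.0]),
            c_fs=np.ones(2), c_hf=np.ones(4),
        )
        mset = DiodeMeasurementSet(totals=np.array([100.0]))
        F = DoseFractionMatrix(F=np.array([[0.7, 0.3]]), flagged=np.array([False]))
        beams = [BeamGeometry(head_id=1, gantry_angle=0.0),
                 BeamGeometry(head_id=2, gantry_angle=180.0)]
        out = apply_weighted_corrections(mset, F, tables, beams, geom, {"AD"})
        assert out.totals[0] == pytest.approx(98.0, abs=1e-12)

    def test_flagged_diodes_unchanged(self, geometry, single_beam_plan, grid_spec):
        grids = simulate_plan(single_beam_plan, grid_spec)
        model = ResponseModel.default(geometry.n_diodes, seed=2)
        _, mset = simulate_measurement(single_beam_plan, grids, geometry, model)
        tables = make_correction_tables(model)
        F = compute_dose_fractions(grids, geometry)
        out = apply_weighted_corrections(
            mset, F, tables, single_beam_plan.beams, geometry)
        assert np.array_equal(out.totals[F.flagged], mset.totals[F.flagged])

    def test_ratio_bounded_by_per_beam_factor_products(
            self, geometry, three_beam_plan, grid_spec, rng):
        from arcqa.geometry import relative_incidence_angle
        grids = simulate_plan(three_beam_plan, grid_spec)
        model = ResponseModel.default(geometry.n_diodes, seed=3)
        _, mset = simulate_measurement(three_beam_plan, grids, geometry, model)
        tables = make_correction_tables(model)
        F = compute_dose_fractions(grids, geometry)
        out = apply_weighted_corrections(
            mset, F, tables, three_beam_plan.beams, geometry)
        ids = np.arange(geometry.n_diodes)
        products = np.column_stack([
            tables.factor_product(
                relative_incidence_angle(geometry, ids, b.gantry_angle))
            for b in three_beam_plan.beams
        ])
        nz = (~F.flagged) & (mset.totals > 1e-9)
        ratio = out.totals[nz] / mset.totals[nz]
        assert np.all(ratio >= products[nz].min(axis=1) - 1e-12)
        assert np.all(ratio <= products[nz].max(axis=1) + 1e-12)

    def test_misaligned_inputs_rejected(self, geometry, single_beam_plan):
        mset = DiodeMeasurementSet(totals=np.ones(geometry.n_diodes))
        F = DoseFractionMatrix(F=np.ones((10, 1)), flagged=np.zeros(10, bool))
        with pytest.raises(ConsistencyError):
            apply_weighted_corrections(
                mset, F, _unit_tables(geometry.n_diodes),
                single_beam_plan.beams, geometry)


class TestFramewiseCorrections:
    def test_unit_tables_return_raw_frame_sums(self, geometry):
        frames = FrameSeries(frames=np.abs(np.random.default_rng(0).normal(
            1.0, 0.1, (5, geometry.n_diodes))))
        angles = [FrameAngleEstimate(i, 10.0 * i, "ok") for i in range(5)]
        out = apply_framewise_corrections(
            frames, angles, _unit_tables(geometry.n_diodes), geometry)
        assert np.allclose(out.totals, frames.totals())

    def test_single_frame_single_factor(self):
        geom = _tiny_geometry(1)
        nodes = np.arange(0.0, 360.0, 90.0)
        tables = CorrectionTables(
            angle_nodes=nodes, c_ad=np.array([0.9, 1.0, 1.0, 1.0]),
            c_id=np.ones(1), fs_nodes=np.array([1.0, 40.0]),
            c_fs=np.ones(2), c_hf=np.ones(4),
        )
        frames = FrameSeries(frames=np.array([[1.0]]))
        out = apply_framewise_corrections(
            frames, [FrameAngleEstimate(0, float(geom.azimuth[0]), "ok")],
            tables, geom, {"AD"})
        assert out.totals[0] == pytest.approx(0.9)

    def test_splitting_a_frame_is_linear(self, geometry):
        rng = np.random.default_rng(1)
        one = np.abs(rng.normal(1.0, 0.2, (1, geometry.n_diodes)))
        whole = FrameSeries(frames=one)
        halves = FrameSeries(frames=np.vstack([one / 2, one / 2]))
        model = ResponseModel.default(geometry.n_diodes, seed=4)
        tables = make_correction_tables(model)
        a = apply_framewise_corrections(
            whole, [FrameAngleEstimate(0, 42.0, "ok")], tables, geometry)
        b = apply_framewise_corrections(
            halves, [FrameAngleEstimate(i, 42.0, "ok") for i in range(2)],
            tables, geometry)
        assert np.allclose(a.totals, b.totals)

    def test_not_ok_frames_pass_through_uncorrected_and_counted(self, geometry):
        frames = FrameSeries(frames=np.ones((2, geometry.n_diodes)))
        model = ResponseModel.default(geometry.n_diodes, seed=5)
        tables = make_correction_tables(model)
        angles = [FrameAngleEstimate(0, 42.0, "ok"),
                  FrameAngleEstimate(1, None, "ambiguous")]
        out = apply_framewise_corrections(frames, angles, tables, geometry)
        corrected_part = tables.factor_product(
            (42.0 - geometry.azimuth) % 360.0)
        assert np.allclose(out.totals, corrected_part + 1.0)
        assert out.info["n_uncorrected_frames"] == 1


class TestMethodEquivalence:
    def test_single_beam_static_gantry_collapse(
            self, geometry, single_beam_plan, grid_spec):
        # K = 1, noiseless: the weighted form reduces to the framewise form
        grids = simulate_plan(single_beam_plan, grid_spec)
        model = ResponseModel.default(geometry.n_diodes, seed=3, noise_sd=0.0)
        tables = make_correction_tables(model)
        series, mset = simulate_measurement(single_beam_plan, grids, geometry, model)
        angle = single_beam_plan.beams[0].gantry_angle
        fw = apply_framewise_corrections(
            series, [FrameAngleEstimate(i, angle, "ok")
                     for i in range(series.n_frames)], tables, geometry)
        F = compute_dose_fractions(grids, geometry)
        w = apply_weighted_corrections(
            mset, F, tables, single_beam_plan.beams, geometry)
        m = (~F.flagged) & (w.totals > 1e-12)
        assert np.max(np.abs(fw.totals[m] - w.totals[m]) / w.totals[m]) < 1e-9


class TestMaxCorrectionReduction:
    def test_unit_tables_give_zero(self, geometry):
        assert max_correction_reduction(_unit_tables(geometry.n_diodes)) == 0.0

    @pytest.mark.parametrize("min_product,expected", [
        (0.5, 100.0),
        (0.813, 1.0 / 0.813 * 100 - 100),  # about 23.0%
    ])
    def test_reciprocal_of_minimum_product(self, min_product, expected):
        nodes = np.arange(0.0, 360.0, 90.0)
        tables = CorrectionTables(
            angle_nodes=nodes, c_ad=np.array([min_product, 1.0, 1.1, 1.0]),
            c_id=np.ones(3), fs_nodes=np.array([1.0, 40.0]),
            c_fs=np.ones(2), c_hf=np.ones(4),
        )
        assert max_correction_reduction(tables) == pytest.approx(expected)
        assert max_correction_reduction(tables, {"AD"}) == pytest.approx(expected)


class TestTablesContainer:
    def test_csv_round_trip(self, tmp_path):
        model = ResponseModel.default(25, seed=9)
        t = make_correction_tables(model, angle_step=5.0)
        t.to_csv_dir(tmp_path)
        back = CorrectionTables.from_csv_dir(tmp_path)
        assert np.array_equal(back.c_ad, t.c_ad)
        assert np.array_equal(back.c_id, t.c_id)
        assert np.array_equal(back.c_fs, t.c_fs)

    def test_field_size_outside_domain_rejected(self):
        t = _unit_tables(4)
        with pytest.raises(TableEvaluationError):
            t.fs_at(100.0)

    def test_periodic_interpolation_wraps(self):
        nodes = np.arange(0.0, 360.0, 90.0)
        t = CorrectionTables(
            angle_nodes=nodes, c_ad=np.array([1.0, 2.0, 3.0, 2.0]),
            c_id=np.ones(1), fs_nodes=np.array([1.0, 40.0]),
            c_fs=np.ones(2), c_hf=np.ones(4),
        )
        assert t.ad_at(315.0) == pytest.approx(1.5)  # halfway 270 -> 360(=0)
        assert t.ad_at(-45.0) == pytest.approx(1.5)

    def test_nonpositive_values_rejected(self):
        nodes = np.arange(0.0, 360.0, 90.0)
        with pytest.raises(ValueError):
            CorrectionTables(
                angle_nodes=nodes, c_ad=np.array([1.0, 0.0, 1.0, 1.0]),
                c_id=np.ones(1), fs_nodes=np.array([1.0, 40.0]),
                c_fs=np.ones(2), c_hf=np.ones(4),
            )
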