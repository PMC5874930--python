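"""Synthetic planned-dose and diode-measurement generator.

Stands in for the treatment planning system's per-beam dose grids and the
device's 50-ms measurement stream, with the statistical structure the
downstream analysis assumes:

* a simple Co-60 pencil/broad-beam dose model (inverse square, effective
  attenuation along the radiological path through the PMMA cylinder,
  error-function penumbra at the rectangular aperture edges);
* a diode response model with a smooth angular dependence, a per-diode
  sensitivity spread, a field-size dependence, and a global systematic
  over-response emulating the magnetic-field effect (about +5% median in
  the motivating measurements);
* per-frame multiplicative Gaussian noise, all randomness through one
  seeded generator.

The physics constants are plausible Co-60 values, configurable, not
device-measured: SAD 105 cm, effective attenuation 0.0657 cm^-1 in water
scaled by relative density, penumbra sigma 3 mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.special import erf

from .formats import DoseGrid, PlanSpec
from .geometry import (
    ArrayConfig,
    BeamGeometry,
    DiodeArrayGeometry,
    GeometryConfigError,
    beam_source_position,
    build_geometry,
    relative_incidence_angle,
)
from .measurement import ConsistencyError, DiodeMeasurementSet, FrameSeries

__all__ = [
    "MediumConfig",
    "GridSpec",
    "ResponseModel",
    "beam_dose_at_points",
    "simulate_beam_dose",
    "simulate_plan",
    "simulate_measurement",
    "make_correction_tables",
    "split_plan",
    "random_plan",
    "generate_scenario",
]


@dataclass(frozen=True)
class MediumConfig:
    """Phantom medium and beam-model constants.

    ``density`` is the physical PMMA relative density used for "truth"
    grids; ``tps_density`` optionally overrides it when generating
    TPS-style grids, emulating the commissioning practice of tuning the
    phantom's electron density in the planning system (1.125 g cm^-3 is
    the tuned value the motivating study used).  ``None`` disables the
    override so reference and truth coincide.
    """

    density: float = 1.19             # PMMA relative to water
    tps_density: float | None = None  # e.g. 1.125 to emulate tuned commissioning
    mu_eff_water: float = 0.0657      # cm^-1, Co-60 broad-beam effective
    penumbra_sigma: float = 0.3       # cm at the isocenter plane
    outer_radius: float = 13.3        # cm, phantom lateral surface
    length: float = 21.0              # cm, phantom axial extent


@dataclass(frozen=True)
class GridSpec:
    """Shape of a dose grid to generate: origin (cm), spacing (cm), shape."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    @classmethod
    def covering_phantom(
        cls, medium: MediumConfig | None = None, spacing: float = 0.7
    ) -> "GridSpec":
        """A symmetric grid covering the phantom with margin, given spacing."""
        medium = medium or MediumConfig()
        # margins sized so a 3 x 3 mm gamma search window around edge
        # diodes still falls inside the grid
        half_xy = medium.outer_radius + 1.5
        half_z = medium.length / 2 + 1.5
        n_xy = 2 * int(round(half_xy / spacing)) + 1
        n_z = 2 * int(round(half_z / spacing)) + 1
        return cls(
            origin=(-spacing * (n_xy - 1) / 2, -spacing * (n_xy - 1) / 2,
                    -spacing * (n_z - 1) / 2),
            spacing=(spacing, spacing, spacing),
            shape=(n_xy, n_xy, n_z),
        )

    def points(self) -> np.ndarray:
        axes = [
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def covers_isocenter(self) -> bool:
        return all(
            self.origin[a] <= 0.0 <= self.origin[a] + self.spacing[a] * (self.shape[a] - 1)
            for a in range(3)
        )


def _default_angular(phi_deg: np.ndarray) -> np.ndarray:
    """Default diode angular response: smooth, periodic, mildly asymmetric
    between entry (0 deg) and exit (180 deg), about +/-3% overall range."""
    p = np.deg2rad(phi_deg)
    return 1.0 + 0.02 * np.cos(p) + 0.01 * np.cos(2 * p) + 0.005 * np.sin(p)


def _default_field_size(eq_square_cm: np.ndarray) -> np.ndarray:
    """Default field-size response: weakly increasing with equivalent square."""
    a = np.asarray(eq_square_cm, dtype=float)
    return 1.0 + 0.001 * (a - 10.0)


@dataclass
class ResponseModel:
    """Multiplicative diode response model.

    Per frame and diode the simulated increment is::

        share * (1 + magnetic_bias) * a(phi) * s_i * f(A) * (1 + eps)

    with ``share`` the planned per-frame dose, ``a`` the angular curve over
    the beam-relative incidence angle, ``s_i`` the diode's sensitivity,
    ``f`` the field-size curve over the equivalent square, and
    ``eps ~ N(0, noise_sd)``.
    """

    sensitivity: np.ndarray
    angular_curve: Callable[[np.ndarray], np.ndarray] = _default_angular
    field_size_curve: Callable[[np.ndarray], np.ndarray] = _default_field_size
    magnetic_bias: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)
        if np.any(self.sensitivity <= 0) or not np.all(np.isfinite(self.sensitivity)):
            raise ValueError("sensitivity factors must be strictly positive")
        if self.magnetic_bias <= -1:
            raise ValueError("magnetic_bias must exceed -1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def identity(cls, n_diodes: int) -> "ResponseModel":
        """Unit response everywhere: a = f = 1, s_i = 1, no bias, no noise."""
        return cls(
            sensitivity=np.ones(n_diodes),
            angular_curve=lambda p: np.ones_like(np.asarray(p, dtype=float)),
            field_size_curve=lambda a: np.ones_like(np.asarray(a, dtype=float)),
        )

    @classmethod
    def default(
        cls,
        n_diodes: int,
        seed: int = 0,
        magnetic_bias: float = 0.05,
        noise_sd: float = 0.01,
        sensitivity_sigma: float = 0.005,
    ) -> "ResponseModel":
        """The study-condition model: +5% systematic over-response, 1% frame
        noise, 0.5% lognormal per-diode sensitivity spread."""
        rng = np.random.default_rng(seed)
        return cls(
            sensitivity=rng.lognormal(0.0, sensitivity_sigma, n_diodes),
            magnetic_bias=magnetic_bias,
            noise_sd=noise_sd,
            seed=seed,
        )


# ---------------------------------------------------------------------------
# Beam dose model
# ---------------------------------------------------------------------------

def beam_dose_at_points(
    beam: BeamGeometry,
    points: np.ndarray,
    medium: MediumConfig | None = None,
    density: float | None = None,
) -> np.ndarray:
    """Dose (cGy) of one beam at arbitrary Cartesian points (cm).

    dose = output_rate * t/60 * (SAD/d)^2 * exp(-mu_w * rho * depth) * T,
    where ``depth`` is the geometric path through the finite cylinder from
    the beam entry point to the query point and ``T`` the aperture
    transmission with error-function penumbra, evaluated in the divergent
    beam frame scaled back to the isocenter plane.
    """
    medium = medium or MediumConfig()
    rho = medium.density if density is None else density
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    src = beam_source_position(beam)
    d = pts - src
    dist = np.linalg.norm(d, axis=1)
    dist = np.maximum(dist, 1e-9)
    u = d / dist[:, None]

    # path length inside the finite cylinder x^2 + y^2 <= R^2, |z| <= L/2
    r_out = medium.outer_radius
    a = u[:, 0] ** 2 + u[:, 1] ** 2
    b = 2.0 * (src[0] * u[:, 0] + src[1] * u[:, 1])
    c = src[0] ** 2 + src[1] ** 2 - r_out**2
    disc = b**2 - 4.0 * a * c
    hit = (disc > 0) & (a > 1e-12)
    sq = np.sqrt(np.where(hit, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(hit, (-b - sq) / (2 * a), np.inf)
        t2 = np.where(hit, (-b + sq) / (2 * a), -np.inf)
    half_l = medium.length / 2.0
    uz = u[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        ta = (-half_l - src[2]) / np.where(np.abs(uz) > 1e-12, uz, np.nan)
        tb = (half_l - src[2]) / np.where(np.abs(uz) > 1e-12, uz, np.nan)
    tz_lo = np.where(np.isnan(ta), -np.inf, np.minimum(ta, tb))
    tz_hi = np.where(np.isnan(ta), np.inf, np.maximum(ta, tb))
    t_in = np.maximum(t1, tz_lo)
    t_out = np.minimum(np.minimum(t2, tz_hi), dist)
    depth = np.clip(t_out - t_in, 0.0, None)

    # aperture transmission in the divergent frame
    g = math.radians(beam.gantry_angle)
    axis = np.array([-math.sin(g), -math.cos(g), 0.0])   # source -> isocenter
    e_u = np.array([math.cos(g), -math.sin(g), 0.0])     # in-plane lateral
    d_axis = d @ axis
    valid = d_axis > 1e-9
    scale = np.where(valid, beam.source_axis_distance / np.where(valid, d_axis, 1.0), 0.0)
    u_iso = (d @ e_u) * scale
    v_iso = d[:, 2] * scale
    w_half, l_half = beam.aperture[0] / 2.0, beam.aperture[1] / 2.0
    s2 = medium.penumbra_sigma * math.sqrt(2.0)
    trans_u = 0.5 * (erf((w_half - u_iso) / s2) + erf((w_half + u_iso) / s2))
    trans_v = 0.5 * (erf((l_half - v_iso) / s2) + erf((l_half + v_iso) / s2))
    transmission = np.where(valid, trans_u * trans_v, 0.0)

    inv_sq = (beam.source_axis_distance / dist) ** 2
    dose = (
        beam.output_rate * beam.beam_on_time / 60.0
        * inv_sq
        * np.exp(-medium.mu_eff_water * rho * depth)
        * transmission
    )
    return np.clip(dose, 0.0, None)


def simulate_beam_dose(
    beam: BeamGeometry,
    grid_spec: GridSpec,
    medium: MediumConfig | None = None,
    tps: bool = False,
) -> DoseGrid:
    """Evaluate the beam model on a regular grid; deterministic.

    With ``tps=True`` and a ``tps_density`` override set, the grid is
    computed with the tuned density, emulating a planning system
    commissioned to a different effective medium than physical truth.
    """
    medium = medium or MediumConfig()
    if not grid_spec.covers_isocenter():
        raise GeometryConfigError("grid_spec must cover the isocenter")
    density = medium.density
    if tps and medium.tps_density is not None:
        density = medium.tps_density
    vals = beam_dose_at_points(beam, grid_spec.points(), medium, density=density)
    return DoseGrid(
        values=vals.reshape(grid_spec.shape),
        origin=grid_spec.origin,
        spacing=grid_spec.spacing,
        beam_label=f"head{beam.head_id}",
    )


def simulate_plan(
    plan: PlanSpec,
    grid_spec: GridSpec,
    medium: MediumConfig | None = None,
    tps: bool = False,
) -> list[DoseGrid]:
    """One grid per beam of the plan (plan sum = voxelwise addition)."""
    return [simulate_beam_dose(b, grid_spec, medium, tps=tps) for b in plan.beams]


def plan_sum(grids: Sequence[DoseGrid]) -> DoseGrid:
    """Voxelwise sum of per-beam grids sharing one coordinate frame."""
    first = grids[0]
    total = np.zeros_like(first.values)
    for g in grids:
        if g.shape != first.shape or g.origin != first.origin or g.spacing != first.spacing:
            raise ConsistencyError("grids must share one coordinate frame")
        total += g.values
    return DoseGrid(total, first.origin, first.spacing, beam_label="plan-sum")


# ---------------------------------------------------------------------------
# Measurement simulation
# ---------------------------------------------------------------------------

def simulate_measurement(
    plan: PlanSpec,
    grids: Sequence[DoseGrid] | None,
    geometry: DiodeArrayGeometry,
    model: ResponseModel,
    simultaneous: bool = True,
    seed: int | None = None,
    frame_duration_ms: float = 50.0,
    medium: MediumConfig | None = None,
) -> tuple[FrameSeries, DiodeMeasurementSet]:
    """Simulate the device's frame stream and accumulated totals.

    Per-beam planned diode doses come from trilinear interpolation of the
    supplied ``grids`` (one per beam), or from direct evaluation of the
    beam model when ``grids`` is None.  Each beam's dose is spread evenly
    over its own beam-on frames, either with all beams running at once
    (``simultaneous=True``) or as sequential single-beam segments.  Totals
    equal the frame sums exactly; fixed seeds reproduce bit-identical
    output.
    """
    if grids is not None and len(grids) != len(plan.beams):
        raise ConsistencyError(
            f"{len(grids)} grids supplied for {len(plan.beams)} beams"
        )
    positions = geometry.positions()
    n = geometry.n_diodes
    if model.sensitivity.size != n:
        raise ConsistencyError("response model sized for a different geometry")

    # planned dose per diode per beam, with per-beam response multipliers
    d_ik = np.empty((len(plan.beams), n))
    mult = np.empty_like(d_ik)
    for k, beam in enumerate(plan.beams):
        if grids is not None:
            d_ik[k] = grids[k].interpolate(positions)
        else:
            d_ik[k] = beam_dose_at_points(beam, positions, medium)
        phi = relative_incidence_angle(geometry, np.arange(n), beam.gantry_angle)
        mult[k] = (
            (1.0 + model.magnetic_bias)
            * model.angular_curve(phi)
            * model.sensitivity
            * model.field_size_curve(np.array(beam.equivalent_square))
        )

    frames_per_beam = [
        max(1, int(math.ceil(b.beam_on_time * 1000.0 / frame_duration_ms)))
        if b.beam_on_time > 0 else 0
        for b in plan.beams
    ]
    rng = np.random.default_rng(model.seed if seed is None else seed)

    if simultaneous:
        n_frames = max(frames_per_beam, default=0) or 1
        frames = np.zeros((n_frames, n))
        active: list[set[int]] = [set() for _ in range(n_frames)]
        for k, beam in enumerate(plan.beams):
            fk = frames_per_beam[k]
            if fk == 0:
                continue
            share = d_ik[k] * mult[k] / fk
            eps = rng.normal(0.0, model.noise_sd, (fk, n)) if model.noise_sd > 0 else 0.0
            frames[:fk] += np.clip(share[None, :] * (1.0 + eps), 0.0, None)
            for f_idx in range(fk):
                active[f_idx].add(beam.head_id)
    else:
        n_frames = sum(frames_per_beam) or 1
        frames = np.zeros((n_frames, n))
        active = [set() for _ in range(n_frames)]
        offset = 0
        for k, beam in enumerate(plan.beams):
            fk = frames_per_beam[k]
            if fk == 0:
                continue
            share = d_ik[k] * mult[k] / fk
            eps = rng.normal(0.0, model.noise_sd, (fk, n)) if model.noise_sd > 0 else 0.0
            frames[offset:offset + fk] = np.clip(share[None, :] * (1.0 + eps), 0.0, None)
            for f_idx in range(offset, offset + fk):
                active[f_idx].add(beam.head_id)
            offset += fk

    series = FrameSeries(
        frames=frames,
        frame_duration_ms=frame_duration_ms,
        active_beams=[tuple(sorted(s)) for s in active],
    )
    mset = DiodeMeasurementSet(
        totals=series.totals(),
        geometry_name=geometry.name,
        plan_id=plan.plan_id,
        corrected=False,
        method="raw",
        frames=series,
    )
    return series, mset


def make_correction_tables(
    model: ResponseModel,
    angle_step: float = 1.0,
    field_sizes: np.ndarray | None = None,
    heterogeneity_curve: Callable[[np.ndarray], np.ndarray] | None = None,
):
    """Reciprocal factor tables for a response model.

    C_AD(phi) = 1/a(phi), C_ID,i = 1/s_i, C_FS(A) = 1/f(A); C_HF comes from
    a configurable heterogeneity curve (default: unity).  The tables are
    sampled on regular grids and carry a linear (periodic in angle)
    interpolation rule.  The systematic over-response term is deliberately
    *not* inverted: the real device's factor tables are indexed by angle,
    diode and field size only, so a global offset has no slot to live in.
    """
    from .corrections import CorrectionTables

    angle_nodes = np.arange(0.0, 360.0, angle_step)
    a_vals = np.asarray(model.angular_curve(angle_nodes), dtype=float)
    if np.any(a_vals <= 0):
        raise ValueError("angular response must be strictly positive")
    field_sizes = (
        np.arange(1.0, 41.0) if field_sizes is None else np.asarray(field_sizes, float)
    )
    f_vals = np.asarray(model.field_size_curve(field_sizes), dtype=float)
    if np.any(f_vals <= 0):
        raise ValueError("field-size response must be strictly positive")
    hf = (
        np.asarray(heterogeneity_curve(angle_nodes), dtype=float)
        if heterogeneity_curve is not None
        else np.ones_like(angle_nodes)
    )
    if np.any(hf <= 0):
        raise ValueError("heterogeneity factors must be strictly positive")
    return CorrectionTables(
        angle_nodes=angle_nodes,
        c_ad=1.0 / a_vals,
        c_id=1.0 / model.sensitivity,
        fs_nodes=field_sizes,
        c_fs=1.0 / f_vals,
        c_hf=hf,
        interpolation="linear-periodic",
    )


def split_plan(plan: PlanSpec) -> list[PlanSpec]:
    """Separate a multi-head plan into single-head plans, beams unaltered.

    Labels record the parent: ``<plan_id>#head<k>``.  A one-beam plan comes
    back as a singleton equal to the input.
    """
    if len(plan.beams) == 1:
        return [plan]
    return [
        PlanSpec(
            plan_id=f"{plan.plan_id}#head{b.head_id}",
            beams=[b],
            prescription_note=plan.prescription_note,
        )
        for b in plan.beams
    ]


# ---------------------------------------------------------------------------
# Scenario generation
# ---------------------------------------------------------------------------

def random_plan(rng: np.random.Generator, plan_id: str, n_beams: int = 3) -> PlanSpec:
    """A random n-beam plan: heads 120 degrees apart at a random base angle,
    moderate rectangular apertures, beam-on times of a few seconds."""
    base = float(rng.uniform(0.0, 360.0))
    beams = [
        BeamGeometry.from_head1_angle(
            head_id=k,
            head1_angle=base,
            aperture=(float(rng.uniform(5.0, 15.0)), float(rng.uniform(5.0, 15.0))),
            beam_on_time=float(rng.uniform(3.0, 8.0)),
        )
        for k in range(1, n_beams + 1)
    ]
    return PlanSpec(plan_id=plan_id, beams=beams)


def generate_scenario(
    n_plans: int = 19,
    seed: int = 0,
    geometry: DiodeArrayGeometry | None = None,
    model: ResponseModel | None = None,
    grid_spacing: float = 0.7,
    medium: MediumConfig | None = None,
    simultaneous: bool = True,
) -> dict:
    """Generate a full multi-plan study: plans, per-beam TPS grids, and
    raw measurements, all from one seeded generator.

    The default 19 three-head plans on the 1386-diode array give the
    26,334 diode-record structure of a full QA campaign.
    """
    medium = medium or MediumConfig()
    geometry = geometry or build_geometry(ArrayConfig())
    model = model or ResponseModel.default(geometry.n_diodes, seed=seed)
    rng = np.random.default_rng(seed)
    spec = GridSpec.covering_phantom(medium, spacing=grid_spacing)
    out = {"geometry": geometry, "model": model, "plans": [], "grids": [],
           "measurements": [], "seed": seed}
    for p in range(n_plans):
        plan = random_plan(rng, plan_id=f"plan{p:03d}")
        grids = simulate_plan(plan, spec, medium, tps=True)
        # the device responds to the physical dose, the reference grids to
        # the (possibly density-tuned) TPS dose
        truth = grids if medium.tps_density is None else simulate_plan(plan, spec, medium)
        _, mset = simulate_measurement(
            plan, truth, geometry, model,
            simultaneous=simultaneous,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out["plans"].append(plan)
        out["grids"].append(grids)
        out["measurements"].append(mset)
    return out
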