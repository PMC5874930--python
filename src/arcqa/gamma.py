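"""Gamma index between planned dose and measured diode doses on the
unwrapped cylindrical detector surface.

Each evaluated diode's gamma is the minimum, over reference surface points
within a search radius, of

    sqrt( (dose difference / dose criterion)^2 + (distance / DTA)^2 )

with the dose criterion referenced to the maximum reference dose (global
normalization, the default) or to the local reference dose.  Distances are
measured on the unwrapped cylinder (arc length at the detector radius, z)
with azimuthal wraparound.  Diodes whose reference dose falls below the
threshold percentage of the global maximum are excluded from evaluation;
a 10% global threshold is the conventional setting.

Only the reference distribution is searched (sampled on a fine surface
lattice from the plan grid); the measured diode values are taken as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats import DoseGrid
from .geometry import DiodeArrayGeometry
from .measurement import ConsistencyError, DiodeMeasurementSet

__all__ = ["GammaCriteria", "GammaResult", "gamma_analysis", "gamma_brute_force"]

#: gamma values are capped here after the search
GAMMA_CAP = 10.0
#: search radius in units of the DTA criterion
SEARCH_FACTOR = 3.0
#: surface sampling step of the reference lattice, mm
DEFAULT_STEP_MM = 0.1


@dataclass(frozen=True)
class GammaCriteria:
    """Dose/DTA criteria: e.g. GammaCriteria(3, 3) is 3%/3 mm."""

    dose_percent: float
    dta_mm: float
    threshold_percent: float = 10.0
    normalization: str = "global"

    def __post_init__(self):
        if self.dose_percent <= 0 or self.dta_mm <= 0 or self.threshold_percent <= 0:
            raise ValueError("gamma criteria must be strictly positive")
        if self.normalization not in ("global", "local"):
            raise ValueError("normalization must be 'global' or 'local'")

    def label(self) -> str:
        return f"{self.dose_percent:g}%/{self.dta_mm:g} mm"


@dataclass
class GammaResult:
    """Per-diode gamma values (NaN where excluded) and the pass rate."""

    gamma: np.ndarray
    evaluated: np.ndarray
    criteria: GammaCriteria

    @property
    def n_evaluated(self) -> int:
        return int(self.evaluated.sum())

    @property
    def pass_rate(self) -> float:
        """Percent of evaluated diodes with gamma <= 1."""
        n = self.n_evaluated
        if n == 0:
            return float("nan")
        return 100.0 * float(np.sum(self.gamma[self.evaluated] <= 1.0)) / n


def _window_offsets(dta_mm: float, step_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Surface-lattice offsets (arc, z) in mm within the search radius."""
    radius = SEARCH_FACTOR * dta_mm
    k = int(np.floor(radius / step_mm))
    line = np.arange(-k, k + 1) * step_mm
    ds, dz = np.meshgrid(line, line, indexing="ij")
    mask = ds**2 + dz**2 <= radius**2 + 1e-12
    return ds[mask], dz[mask]


def _reference_at_diodes(
    reference: DoseGrid | np.ndarray, geometry: DiodeArrayGeometry
) -> np.ndarray:
    if isinstance(reference, DoseGrid):
        ref = reference.interpolate(geometry.positions())
        if not np.any(ref > 0):
            raise ConsistencyError("reference grid does not cover the detector surface")
        return ref
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (geometry.n_diodes,):
        raise ConsistencyError("reference-at-diodes must align with the geometry")
    return ref


def _measured_values(measured) -> np.ndarray:
    if isinstance(measured, DiodeMeasurementSet):
        return measured.totals
    return np.asarray(measured, dtype=float)


def _surface_window_dose(
    reference: DoseGrid,
    geometry: DiodeArrayGeometry,
    idx: np.ndarray,
    ds_mm: np.ndarray,
    dz_mm: np.ndarray,
) -> np.ndarray:
    """Reference dose at window offsets around diodes ``idx``: (len(idx), M)."""
    r = geometry.detector_radius
    az0 = np.deg2rad(geometry.azimuth[idx])[:, None]
    az = az0 + (ds_mm / 10.0 / r)[None, :]
    z = geometry.z[idx][:, None] + (dz_mm / 10.0)[None, :]
    pts = np.stack(
        [r * np.sin(az), r * np.cos(az), z], axis=-1
    ).reshape(-1, 3)
    return reference.interpolate(pts).reshape(len(idx), ds_mm.size)


def gamma_analysis(
    reference: DoseGrid | np.ndarray,
    measured: DiodeMeasurementSet | np.ndarray,
    geometry: DiodeArrayGeometry,
    criteria: GammaCriteria,
    step_mm: float = DEFAULT_STEP_MM,
) -> GammaResult:
    """Gamma index of measured diode doses against a reference.

    ``reference`` is either a plan-sum :class:`DoseGrid` (the search runs
    over its interpolation onto the cylinder surface, sampled at
    ``step_mm`` within a radius of 3 x DTA) or a per-diode reference
    vector (the search runs over the diode lattice itself).
    """
    m = _measured_values(measured)
    if m.shape != (geometry.n_diodes,):
        raise ConsistencyError("measured values must align with the geometry")
    ref_d = _reference_at_diodes(reference, geometry)
    dmax = float(ref_d.max())
    evaluated = ref_d >= criteria.threshold_percent / 100.0 * dmax
    gamma = np.full(geometry.n_diodes, np.nan)
    idx_all = np.flatnonzero(evaluated)
    if idx_all.size == 0:
        return GammaResult(gamma=gamma, evaluated=evaluated, criteria=criteria)

    if criteria.normalization == "global":
        denom = np.full(geometry.n_diodes, criteria.dose_percent / 100.0 * dmax)
    else:
        denom = criteria.dose_percent / 100.0 * ref_d

    if isinstance(reference, DoseGrid):
        ds_mm, dz_mm = _window_offsets(criteria.dta_mm, step_mm)
        dist2 = (ds_mm**2 + dz_mm**2) / criteria.dta_mm**2
        # chunk so each (diodes x window) dose block stays modest
        chunk = max(1, int(2_000_000 / ds_mm.size))
        for start in range(0, idx_all.size, chunk):
            idx = idx_all[start:start + chunk]
            dose = _surface_window_dose(reference, geometry, idx, ds_mm, dz_mm)
            dterm = (m[idx][:, None] - dose) / denom[idx][:, None]
            g2 = dterm**2 + dist2[None, :]
            gamma[idx] = np.sqrt(g2.min(axis=1))
    else:
        # diode-lattice search: pairwise unwrapped-surface distances
        radius = SEARCH_FACTOR * criteria.dta_mm
        daz = np.deg2rad(
            (geometry.azimuth[:, None] - geometry.azimuth[None, :] + 180.0) % 360.0
            - 180.0
        )
        ds = geometry.detector_radius * daz * 10.0  # mm
        dz = (geometry.z[:, None] - geometry.z[None, :]) * 10.0
        dist = np.hypot(ds, dz)
        dist2 = np.where(dist <= radius, (dist / criteria.dta_mm) ** 2, np.inf)
        dterm = (m[idx_all][:, None] - ref_d[None, :]) / denom[idx_all][:, None]
        g2 = dterm**2 + dist2[idx_all]
        gamma[idx_all] = np.sqrt(g2.min(axis=1))

    gamma[idx_all] = np.minimum(gamma[idx_all], GAMMA_CAP)
    return GammaResult(gamma=gamma, evaluated=evaluated, criteria=criteria)


def gamma_brute_force(
    reference: DoseGrid | np.ndarray,
    measured: DiodeMeasurementSet | np.ndarray,
    geometry: DiodeArrayGeometry,
    criteria: GammaCriteria,
    step_mm: float = DEFAULT_STEP_MM,
    max_diodes: int = 200,
) -> GammaResult:
    """Straightforward exhaustive gamma for validating :func:`gamma_analysis`.

    One diode at a time, a plain scan over every dense surface sample in
    the search window.  Refuses instances beyond ``max_diodes`` evaluated
    diodes: this is an oracle for toy problems, not an engine.
    """
    m = _measured_values(measured)
    ref_d = _reference_at_diodes(reference, geometry)
    dmax = float(ref_d.max())
    evaluated = ref_d >= criteria.threshold_percent / 100.0 * dmax
    if int(evaluated.sum()) > max_diodes:
        raise ValueError(
            f"brute-force gamma refuses {int(evaluated.sum())} diodes "
            f"(> {max_diodes}); use gamma_analysis"
        )
    gamma = np.full(geometry.n_diodes, np.nan)
    r_cm = geometry.detector_radius
    for i in np.flatnonzero(evaluated):
        if criteria.normalization == "global":
            dd = criteria.dose_percent / 100.0 * dmax
        else:
            dd = criteria.dose_percent / 100.0 * ref_d[i]
        best = np.inf
        if isinstance(reference, DoseGrid):
            ds_mm, dz_mm = _window_offsets(criteria.dta_mm, step_mm)
            az = np.deg2rad(geometry.azimuth[i]) + ds_mm / 10.0 / r_cm
            z = geometry.z[i] + dz_mm / 10.0
            pts = np.column_stack([r_cm * np.sin(az), r_cm * np.cos(az), z])
            dose = reference.interpolate(pts)
            for p in range(pts.shape[0]):
                g2 = ((m[i] - dose[p]) / dd) ** 2 + (
                    ds_mm[p] ** 2 + dz_mm[p] ** 2
                ) / criteria.dta_mm**2
                if g2 < best:
                    best = g2
        else:
            for j in range(geometry.n_diodes):
                daz = ((geometry.azimuth[i] - geometry.azimuth[j] + 180.0) % 360.0) - 180.0
                ds = r_cm * np.deg2rad(daz) * 10.0
                dz = (geometry.z[i] - geometry.z[j]) * 10.0
                if ds**2 + dz**2 > (SEARCH_FACTOR * criteria.dta_mm) ** 2 + 1e-12:
                    continue
                g2 = ((m[i] - ref_d[j]) / dd) ** 2 + (ds**2 + dz**2) / criteria.dta_mm**2
                if g2 < best:
                    best = g2
        gamma[i] = min(np.sqrt(best), GAMMA_CAP)
    return GammaResult(gamma=gamma, evaluated=evaluated, criteria=criteria)
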