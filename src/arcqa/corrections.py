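"""Diode correction factors and their two application methods.

Four multiplicative factors correct a diode reading: angular dependence
(C_AD, indexed by the beam-relative incidence angle), individual diode
sensitivity (C_ID), field size (C_FS, indexed by the equivalent square),
and phantom heterogeneity (C_HF, angle-indexed).  They can be applied

* per measurement frame, at the angle the virtual inclinometer estimated
  for that frame (single-beam deliveries only), or
* to the accumulated total, weighting each beam's factor product by the
  fraction of the planned dose that beam contributes to the diode:

      D_corr,i = D_uncorr,i * sum_k F_ik * C_AD,ik * C_ID,ik * C_FS,ik * C_HF,ik

  which is what makes corrections applicable to simultaneous multi-beam
  deliveries where the inclinometer is undefined.

The default factor selection is {AD, ID, HF}: the field-size factor
requires a separate field-size-detection step and depends on the delivery
mode, so it is selectable but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .formats import DoseGrid
from .geometry import BeamGeometry, DiodeArrayGeometry, relative_incidence_angle
from .inclinometer import FrameAngleEstimate
from .measurement import ConsistencyError, DiodeMeasurementSet, FrameSeries

__all__ = [
    "CorrectionTables",
    "DoseFractionMatrix",
    "DEFAULT_FACTORS",
    "compute_dose_fractions",
    "apply_weighted_corrections",
    "apply_framewise_corrections",
    "max_correction_reduction",
]

DEFAULT_FACTORS = frozenset({"AD", "ID", "HF"})
_KNOWN_FACTORS = frozenset({"AD", "ID", "FS", "HF"})


class TableEvaluationError(ValueError):
    """Raised when a table does not cover a required evaluation point."""


def _interp_periodic(nodes: np.ndarray, values: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Linear interpolation on an angle table with 360-degree wraparound."""
    q = np.asarray(query, dtype=float) % 360.0
    ext_nodes = np.concatenate([nodes, [nodes[0] + 360.0]])
    ext_vals = np.concatenate([values, [values[0]]])
    return np.interp(q, ext_nodes, ext_vals)


@dataclass
class CorrectionTables:
    """Sampled factor tables with their interpolation rule.

    ``c_ad`` and ``c_hf`` are sampled on ``angle_nodes`` (degrees, covering
    [0, 360) with periodic linear interpolation); ``c_id`` is one scalar
    per diode (nearest = exact lookup); ``c_fs`` is sampled on ``fs_nodes``
    (equivalent-square cm, linear, no extrapolation).
    """

    angle_nodes: np.ndarray
    c_ad: np.ndarray
    c_id: np.ndarray
    fs_nodes: np.ndarray
    c_fs: np.ndarray
    c_hf: np.ndarray
    interpolation: str = "linear-periodic"

    def __post_init__(self):
        for name in ("angle_nodes", "c_ad", "c_id", "fs_nodes", "c_fs", "c_hf"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("c_ad", "c_id", "c_fs", "c_hf"):
            v = getattr(self, name)
            if np.any(v <= 0) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} values must be strictly positive and finite")
        if self.c_ad.shape != self.angle_nodes.shape or self.c_hf.shape != self.angle_nodes.shape:
            raise ValueError("angle tables must match angle_nodes")
        if self.c_fs.shape != self.fs_nodes.shape:
            raise ValueError("c_fs must match fs_nodes")
        if self.angle_nodes[0] != 0.0 or self.angle_nodes[-1] >= 360.0:
            raise ValueError("angle_nodes must cover [0, 360) starting at 0")

    @property
    def n_diodes(self) -> int:
        return self.c_id.size

    def ad_at(self, phi_deg: np.ndarray) -> np.ndarray:
        return _interp_periodic(self.angle_nodes, self.c_ad, phi_deg)

    def hf_at(self, phi_deg: np.ndarray) -> np.ndarray:
        return _interp_periodic(self.angle_nodes, self.c_hf, phi_deg)

    def fs_at(self, eq_square: float | np.ndarray) -> np.ndarray:
        q = np.asarray(eq_square, dtype=float)
        if np.any(q < self.fs_nodes[0]) or np.any(q > self.fs_nodes[-1]):
            raise TableEvaluationError(
                f"field size {q} outside table domain "
                f"[{self.fs_nodes[0]}, {self.fs_nodes[-1]}] cm"
            )
        return np.interp(q, self.fs_nodes, self.c_fs)

    def factor_product(
        self,
        phi_deg: np.ndarray,
        selection: Iterable[str] = DEFAULT_FACTORS,
        eq_square: float | None = None,
    ) -> np.ndarray:
        """Per-diode product of the selected factors at incidence angles
        ``phi_deg`` (one angle per diode)."""
        selection = _check_selection(selection)
        out = np.ones(self.n_diodes)
        if "AD" in selection:
            out = out * self.ad_at(phi_deg)
        if "ID" in selection:
            out = out * self.c_id
        if "HF" in selection:
            out = out * self.hf_at(phi_deg)
        if "FS" in selection:
            if eq_square is None:
                raise TableEvaluationError("FS selected but no field size given")
            out = out * self.fs_at(eq_square)
        return out

    # -- CSV round trip (one file per factor) --------------------------------

    def to_csv_dir(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_table(out / "c_ad.csv", "angle_deg", self.angle_nodes, self.c_ad)
        _write_table(out / "c_hf.csv", "angle_deg", self.angle_nodes, self.c_hf)
        _write_table(out / "c_fs.csv", "eq_square_cm", self.fs_nodes, self.c_fs)
        _write_table(out / "c_id.csv", "diode_id", np.arange(self.n_diodes), self.c_id)

    @classmethod
    def from_csv_dir(cls, in_dir: str | Path) -> "CorrectionTables":
        d = Path(in_dir)
        angle_nodes, c_ad = _read_table(d / "c_ad.csv")
        _, c_hf = _read_table(d / "c_hf.csv")
        fs_nodes, c_fs = _read_table(d / "c_fs.csv")
        _, c_id = _read_table(d / "c_id.csv")
        return cls(angle_nodes=angle_nodes, c_ad=c_ad, c_id=c_id,
                   fs_nodes=fs_nodes, c_fs=c_fs, c_hf=c_hf)


def _write_table(path: Path, key: str, nodes: np.ndarray, values: np.ndarray) -> None:
    with open(path, "w") as f:
        f.write(f"{key},value\n")
        for n, v in zip(nodes, values):
            f.write(f"{float(n)!r},{float(v)!r}\n")


def _read_table(path: Path) -> tuple[np.ndarray, np.ndarray]:
    rows = Path(path).read_text().strip().splitlines()[1:]
    pairs = [tuple(float(x) for x in r.split(",")) for r in rows]
    arr = np.array(pairs)
    return arr[:, 0], arr[:, 1]


def _check_selection(selection: Iterable[str]) -> frozenset:
    sel = frozenset(selection)
    unknown = sel - _KNOWN_FACTORS
    if unknown:
        raise ValueError(f"unknown correction factors {sorted(unknown)}")
    return sel


@dataclass
class DoseFractionMatrix:
    """Per-diode, per-beam planned dose fractions F_ik.

    Unflagged rows sum to 1; rows whose total planned dose falls below the
    flag threshold carry F = 0 and receive no correction.
    """

    F: np.ndarray
    flagged: np.ndarray

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        self.flagged = np.asarray(self.flagged, dtype=bool)
        if self.F.ndim != 2 or self.flagged.shape != (self.F.shape[0],):
            raise ConsistencyError("F must be (n_diodes, n_beams) with per-diode flags")
        if np.any(self.F < 0) or np.any(self.F > 1):
            raise ConsistencyError("dose fractions must lie in [0, 1]")
        rows = self.F[~self.flagged].sum(axis=1)
        if rows.size and np.max(np.abs(rows - 1.0)) > 1e-9:
            raise ConsistencyError("unflagged dose-fraction rows must sum to 1")

    @property
    def n_beams(self) -> int:
        return self.F.shape[1]


def compute_dose_fractions(
    grids: Sequence[DoseGrid],
    geometry: DiodeArrayGeometry,
    eps_cgy: float = 1e-3,
) -> DoseFractionMatrix:
    """F_ik = D_ik / sum_k D_ik from trilinear interpolation of the
    per-beam planned grids at the diode positions.

    Diodes whose summed planned dose falls below ``eps_cgy`` are flagged
    (a fraction of nearly nothing is noise, not signal).
    """
    if not grids:
        raise ConsistencyError("at least one beam grid required")
    first = grids[0]
    for g in grids[1:]:
        if g.shape != first.shape or g.origin != first.origin or g.spacing != first.spacing:
            raise ConsistencyError("beam grids must share one coordinate frame")
    pos = geometry.positions()
    d = np.column_stack([g.interpolate(pos) for g in grids])
    total = d.sum(axis=1)
    flagged = total < eps_cgy
    if np.all(flagged):
        raise ConsistencyError("detector surface receives no planned dose from any grid")
    F = np.zeros_like(d)
    F[~flagged] = d[~flagged] / total[~flagged, None]
    return DoseFractionMatrix(F=F, flagged=flagged)


def apply_weighted_corrections(
    mset: DiodeMeasurementSet,
    fractions: DoseFractionMatrix,
    tables: CorrectionTables,
    beams: Sequence[BeamGeometry],
    geometry: DiodeArrayGeometry,
    factor_selection: Iterable[str] = DEFAULT_FACTORS,
) -> DiodeMeasurementSet:
    """Dose-fraction-weighted correction of the accumulated totals.

    Each beam's selected factor product is evaluated at that beam's static
    incidence angle per diode and weighted by F_ik; flagged diodes are
    returned unchanged.
    """
    selection = _check_selection(factor_selection)
    n = mset.n_diodes
    if fractions.F.shape[0] != n or tables.n_diodes != n or geometry.n_diodes != n:
        raise ConsistencyError("measurement, fractions, tables and geometry must align")
    if len(beams) != fractions.n_beams:
        raise ConsistencyError("beam list must align with dose-fraction columns")
    ids = np.arange(n)
    multiplier = np.zeros(n)
    for k, beam in enumerate(beams):
        phi = relative_incidence_angle(geometry, ids, beam.gantry_angle)
        prod = tables.factor_product(phi, selection, eq_square=beam.equivalent_square)
        multiplier += fractions.F[:, k] * prod
    multiplier[fractions.flagged] = 1.0
    out = DiodeMeasurementSet(
        totals=mset.totals * multiplier,
        geometry_name=mset.geometry_name,
        plan_id=mset.plan_id,
        corrected=True,
        method="weighted",
    )
    out.info = {
        "factors": sorted(selection),
        "n_flagged": int(fractions.flagged.sum()),
    }
    return out


def apply_framewise_corrections(
    series: FrameSeries,
    angles: Sequence[FrameAngleEstimate],
    tables: CorrectionTables,
    geometry: DiodeArrayGeometry,
    factor_selection: Iterable[str] = DEFAULT_FACTORS,
    eq_square: float | None = None,
) -> DiodeMeasurementSet:
    """Per-frame correction at the inclinometer-estimated angles.

    Frames whose angle status is not ``ok`` are accumulated uncorrected and
    counted (guessing an angle would silently mis-correct them).  With FS
    selected, a single delivery-wide ``eq_square`` must be supplied.
    """
    selection = _check_selection(factor_selection)
    if len(angles) != series.n_frames:
        raise ConsistencyError("one angle estimate required per frame")
    if tables.n_diodes != series.n_diodes or geometry.n_diodes != series.n_diodes:
        raise ConsistencyError("series, tables and geometry must align")
    ids = np.arange(series.n_diodes)
    totals = np.zeros(series.n_diodes)
    n_uncorrected = 0
    for f_idx, est in enumerate(angles):
        inc = series.frames[f_idx]
        if est.status != "ok":
            totals += inc
            if inc.any():
                n_uncorrected += 1
            continue
        phi = relative_incidence_angle(geometry, ids, est.angle)
        totals += inc * tables.factor_product(phi, selection, eq_square=eq_square)
    out = DiodeMeasurementSet(
        totals=totals,
        geometry_name=geometry.name,
        corrected=True,
        method="framewise",
    )
    out.info = {
        "factors": sorted(selection),
        "n_uncorrected_frames": n_uncorrected,
    }
    return out


def max_correction_reduction(
    tables: CorrectionTables,
    factor_selection: Iterable[str] = DEFAULT_FACTORS,
) -> float:
    """Largest diode over-response (%) the tables can fully correct.

    A reading over-responding by a fraction r needs a combined factor of
    1/(1+r); the strongest available reduction is the minimum combined
    product over all table nodes and diodes, so r_max = 1/min(product) - 1.
    """
    selection = _check_selection(factor_selection)
    min_prod = 1.0
    angle_part = np.ones_like(tables.angle_nodes)
    if "AD" in selection:
        angle_part = angle_part * tables.c_ad
    if "HF" in selection:
        angle_part = angle_part * tables.c_hf
    min_prod *= float(angle_part.min())
    if "ID" in selection:
        min_prod *= float(tables.c_id.min())
    if "FS" in selection:
        min_prod *= float(tables.c_fs.min())
    return (1.0 / min_prod - 1.0) * 100.0
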