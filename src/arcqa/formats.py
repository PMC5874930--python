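"""File formats: DICOM RT Dose, portable grid container, measurement text
dialect, and CSV/JSON reports.

Grid convention
---------------
``DoseGrid.values`` is indexed ``[ix, iy, iz]`` (x fastest-varying in
memory order of a flattened Fortran dump; axis 0 is x).  ``origin`` is the
center of voxel (0, 0, 0) in cm; ``spacing`` is (dx, dy, dz) in cm.  Dose is
always cGy in memory; DICOM files in Gy are converted on read.

Measurement dialect
-------------------
UTF-8 text.  Header lines ``# key: value`` (geometry name, frame duration,
plan id, diode count), then a CSV block with one row per diode
``diode_id,z_cm,azimuth_deg,total_cGy``, then an optional ``# frames``
block with one row per nonzero ``frame_index,diode_id,dose_cGy`` entry.
Human-diffable and sparse-friendly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import yaml

from .geometry import BeamGeometry, DiodeArrayGeometry
from .measurement import ConsistencyError, DiodeMeasurementSet, FrameSeries

__all__ = [
    "DoseGrid",
    "PlanSpec",
    "FormatError",
    "read_rtdose",
    "write_rtdose",
    "read_grid",
    "write_grid",
    "read_measurement",
    "write_measurement",
    "write_report",
    "read_run_config",
]

logger = logging.getLogger(__name__)

GRID_SCHEMA_VERSION = 1


class FormatError(ValueError):
    """Raised for malformed or unsupported file content."""


@dataclass
class DoseGrid:
    """A 3D planned-dose grid for one beam or a plan sum.

    values : (nx, ny, nz) array, cGy, finite and >= 0.
    origin : (x, y, z) of the first voxel center, cm.
    spacing : (dx, dy, dz), cm, strictly positive.
    """

    values: np.ndarray
    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    beam_label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.origin = tuple(float(v) for v in self.origin)
        self.spacing = tuple(float(v) for v in self.spacing)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise FormatError("values must be a 3D array with >= 1 voxel per axis")
        if any(s <= 0 for s in self.spacing):
            raise FormatError("spacing must be strictly positive on all axes")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise FormatError("dose values must be finite and >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinates along each axis, cm."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at (N, 3) Cartesian points, cm.

        Queries outside the grid return 0 (with a logged warning): the
        phantom region of interest is expected to be fully covered, and a
        hard failure on a stray penumbral query would be worse than an
        explicit zero.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        xs, ys, zs = self.axis_coords()
        lo = np.array([xs[0], ys[0], zs[0]])
        hi = np.array([xs[-1], ys[-1], zs[-1]])
        outside = np.any((points < lo) | (points > hi), axis=1)
        if np.any(outside):
            logger.warning(
                "%d of %d interpolation points fall outside grid '%s'; returning 0",
                int(outside.sum()), len(points), self.beam_label,
            )
        # fractional voxel indices, clipped so edge queries stay exact
        frac = (points - lo) / np.array(self.spacing)
        out = _trilinear(self.values, frac)
        out[outside] = 0.0
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, DoseGrid):
            return NotImplemented
        return (
            self.values.shape == other.values.shape
            and np.array_equal(self.values, other.values)
            and self.origin == other.origin
            and self.spacing == other.spacing
            and self.beam_label == other.beam_label
        )


def _trilinear(values: np.ndarray, frac: np.ndarray) -> np.ndarray:
    """Trilinear interpolation at fractional indices, clamped to the grid."""
    nx, ny, nz = values.shape
    f = np.clip(frac, 0.0, [nx - 1, ny - 1, nz - 1])
    i0 = np.minimum(f.astype(int), [max(nx - 2, 0), max(ny - 2, 0), max(nz - 2, 0)])
    t = f - i0
    ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
    tx, ty, tz = t[:, 0], t[:, 1], t[:, 2]
    ix1 = np.minimum(ix + 1, nx - 1)
    iy1 = np.minimum(iy + 1, ny - 1)
    iz1 = np.minimum(iz + 1, nz - 1)
    c000 = values[ix, iy, iz]
    c100 = values[ix1, iy, iz]
    c010 = values[ix, iy1, iz]
    c110 = values[ix1, iy1, iz]
    c001 = values[ix, iy, iz1]
    c101 = values[ix1, iy, iz1]
    c011 = values[ix, iy1, iz1]
    c111 = values[ix1, iy1, iz1]
    c00 = c000 * (1 - tx) + c100 * tx
    c10 = c010 * (1 - tx) + c110 * tx
    c01 = c001 * (1 - tx) + c101 * tx
    c11 = c011 * (1 - tx) + c111 * tx
    c0 = c00 * (1 - ty) + c10 * ty
    c1 = c01 * (1 - ty) + c11 * ty
    return c0 * (1 - tz) + c1 * tz


@dataclass
class PlanSpec:
    """A delivery plan: up to three simultaneous beams on distinct heads."""

    plan_id: str
    beams: list[BeamGeometry]
    prescription_note: str = ""

    def __post_init__(self):
        if not 1 <= len(self.beams) <= 3:
            raise ConsistencyError("a plan carries 1 to 3 beams")
        heads = [b.head_id for b in self.beams]
        if len(set(heads)) != len(heads):
            raise ConsistencyError("beam head_ids must be distinct")


# ---------------------------------------------------------------------------
# DICOM RT Dose
# ---------------------------------------------------------------------------

_AXIS_ALIGNED = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)


def read_rtdose(path: str | Path) -> DoseGrid:
    """Read a DICOM RT Dose file into a :class:`DoseGrid` (cGy, cm).

    Requires an axis-aligned orientation, uniform frame offsets, and a
    DoseGridScaling attribute; anything else raises :class:`FormatError`
    naming the offending attribute.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    if "DoseGridScaling" not in ds:
        raise FormatError("missing attribute DoseGridScaling")
    orient = tuple(float(v) for v in getattr(ds, "ImageOrientationPatient", ()))
    if orient != _AXIS_ALIGNED:
        raise FormatError(
            f"unsupported ImageOrientationPatient {orient}; only axis-aligned "
            "(1,0,0,0,1,0) grids are read"
        )
    offsets = np.atleast_1d(np.asarray(ds.GridFrameOffsetVector, dtype=float))
    if offsets.size < 1:
        raise FormatError("empty GridFrameOffsetVector")
    if offsets.size > 1:
        steps = np.diff(offsets)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-6) or steps[0] <= 0:
            raise FormatError("non-uniform GridFrameOffsetVector")
        dz_mm = float(steps[0])
    else:
        dz_mm = float(getattr(ds, "SliceThickness", 1.0) or 1.0)

    scaling = float(ds.DoseGridScaling)
    # pixel_array drops singleton axes; restore the (frames=z, rows=y,
    # cols=x) layout explicitly
    stored = ds.pixel_array.astype(float).reshape(
        offsets.size, int(ds.Rows), int(ds.Columns))
    dose = stored * scaling
    units = str(getattr(ds, "DoseUnits", "GY")).upper()
    if units == "GY":
        dose *= 100.0  # -> cGy
    elif units != "CGY":
        raise FormatError(f"unsupported DoseUnits {units!r}")

    row_mm, col_mm = (float(v) for v in ds.PixelSpacing)
    ipp = [float(v) for v in ds.ImagePositionPatient]  # mm
    values = np.transpose(dose, (2, 1, 0))  # -> (x, y, z)
    return DoseGrid(
        values=values,
        origin=(ipp[0] / 10.0, ipp[1] / 10.0, (ipp[2] + offsets[0]) / 10.0),
        spacing=(col_mm / 10.0, row_mm / 10.0, dz_mm / 10.0),
        beam_label=str(getattr(ds, "SeriesDescription", "")),
    )


def write_rtdose(grid: DoseGrid, path: str | Path) -> None:
    """Write a :class:`DoseGrid` as a minimal DICOM RT Dose object (Gy)."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.RTDoseStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.SeriesDescription = grid.beam_label
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "BEAM"

    nx, ny, nz = grid.shape
    dose_gy = grid.values / 100.0
    peak = float(dose_gy.max())
    scaling = peak / (2**31 - 1) if peak > 0 else 1e-8
    stored = np.round(dose_gy / scaling).astype(np.uint32)
    ds.DoseGridScaling = scaling
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.ImageOrientationPatient = list(_AXIS_ALIGNED)
    ds.ImagePositionPatient = [
        grid.origin[0] * 10.0, grid.origin[1] * 10.0, grid.origin[2] * 10.0,
    ]
    ds.PixelSpacing = [grid.spacing[1] * 10.0, grid.spacing[0] * 10.0]
    ds.GridFrameOffsetVector = [grid.spacing[2] * 10.0 * k for k in range(nz)]
    ds.PixelData = np.ascontiguousarray(np.transpose(stored, (2, 1, 0))).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


# ---------------------------------------------------------------------------
# Portable HDF5 grid container
# ---------------------------------------------------------------------------

def write_grid(grid: DoseGrid, path: str | Path) -> None:
    """Lossless HDF5 dump of a grid (float64 values, exact metadata)."""
    with h5py.File(str(path), "w") as f:
        f.attrs["schema_version"] = GRID_SCHEMA_VERSION
        f.attrs["origin_cm"] = grid.origin
        f.attrs["spacing_cm"] = grid.spacing
        f.attrs["beam_label"] = grid.beam_label
        f.create_dataset("dose_cGy", data=grid.values, dtype="float64")


def read_grid(path: str | Path) -> DoseGrid:
    with h5py.File(str(path), "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != GRID_SCHEMA_VERSION:
            raise FormatError(
                f"grid container schema version {version} != {GRID_SCHEMA_VERSION}"
            )
        return DoseGrid(
            values=f["dose_cGy"][()],
            origin=tuple(f.attrs["origin_cm"]),
            spacing=tuple(f.attrs["spacing_cm"]),
            beam_label=str(f.attrs["beam_label"]),
        )


# ---------------------------------------------------------------------------
# Measurement text dialect
# ---------------------------------------------------------------------------

def write_measurement(
    mset: DiodeMeasurementSet,
    path: str | Path,
    geometry: DiodeArrayGeometry | None = None,
) -> None:
    """Write a measurement set in the text dialect (optionally with frames)."""
    lines = [
        f"# geometry: {mset.geometry_name}",
        f"# plan_id: {mset.plan_id}",
        f"# corrected: {str(mset.corrected).lower()}",
        f"# method: {mset.method}",
        f"# n_diodes: {mset.n_diodes}",
    ]
    if mset.frames is not None:
        lines.append(f"# frame_duration_ms: {mset.frames.frame_duration_ms!r}")
        lines.append(f"# n_frames: {mset.frames.n_frames}")
    lines.append("diode_id,z_cm,azimuth_deg,total_cGy")
    z = geometry.z if geometry is not None else np.zeros(mset.n_diodes)
    az = geometry.azimuth if geometry is not None else np.zeros(mset.n_diodes)
    for i in range(mset.n_diodes):
        lines.append(f"{i},{float(z[i])!r},{float(az[i])!r},{float(mset.totals[i])!r}")
    if mset.frames is not None:
        lines.append("# frames")
        lines.append("frame_index,diode_id,dose_cGy")
        fi, di = np.nonzero(mset.frames.frames)
        for f_idx, d_idx in zip(fi, di):
            lines.append(
                f"{f_idx},{d_idx},{float(mset.frames.frames[f_idx, d_idx])!r}"
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_measurement(
    path: str | Path,
    geometry: DiodeArrayGeometry | None = None,
) -> DiodeMeasurementSet:
    """Parse the measurement dialect; validates counts against ``geometry``."""
    text = Path(path).read_text(encoding="utf-8").splitlines()
    header: dict[str, str] = {}
    i = 0
    while i < len(text) and text[i].startswith("#"):
        body = text[i][1:].strip()
        if ":" not in body:
            raise FormatError(f"malformed header at line {i + 1}: {text[i]!r}")
        key, _, value = body.partition(":")
        header[key.strip()] = value.strip()
        i += 1
    if i >= len(text) or not text[i].startswith("diode_id,"):
        raise FormatError(f"missing diode table header at line {i + 1}")
    i += 1

    n_declared = int(header.get("n_diodes", -1))
    totals: list[float] = []
    while i < len(text) and text[i] and not text[i].startswith("#"):
        parts = text[i].split(",")
        if len(parts) != 4:
            raise FormatError(f"malformed diode row at line {i + 1}: {text[i]!r}")
        totals.append(float(parts[3]))
        i += 1
    if n_declared >= 0 and len(totals) != n_declared:
        raise ConsistencyError(
            f"header declares {n_declared} diodes but {len(totals)} rows present"
        )
    if geometry is not None and len(totals) != geometry.n_diodes:
        raise ConsistencyError(
            f"file has {len(totals)} diodes, geometry "
            f"'{geometry.name}' has {geometry.n_diodes}"
        )

    frames = None
    if i < len(text) and text[i].strip() == "# frames":
        i += 1
        if i >= len(text) or not text[i].startswith("frame_index,"):
            raise FormatError(f"missing frame table header at line {i + 1}")
        i += 1
        entries = []
        while i < len(text) and text[i]:
            parts = text[i].split(",")
            if len(parts) != 3:
                raise FormatError(f"malformed frame row at line {i + 1}: {text[i]!r}")
            entries.append((int(parts[0]), int(parts[1]), float(parts[2])))
            i += 1
        n_frames = int(header.get(
            "n_frames", max((e[0] for e in entries), default=-1) + 1))
        arr = np.zeros((max(n_frames, 1), len(totals)))
        for f_idx, d_idx, dose in entries:
            arr[f_idx, d_idx] = dose
        frames = FrameSeries(
            frames=arr,
            frame_duration_ms=float(header.get("frame_duration_ms", 50.0)),
        )

    mset = DiodeMeasurementSet(
        totals=np.array(totals),
        geometry_name=header.get("geometry", "unknown"),
        plan_id=header.get("plan_id", ""),
        corrected=header.get("corrected", "false") == "true",
        method=header.get("method", "raw"),
        frames=frames,
    )
    if not mset.check_frame_totals(rtol=1e-6):
        mset.frame_total_mismatch = True
        logger.warning("frame sums disagree with totals in %s", path)
    return mset


# ---------------------------------------------------------------------------
# Reports and run configuration
# ---------------------------------------------------------------------------

def write_report(results: dict, out_dir: str | Path) -> None:
    """Write the analysis bundle: CSV tables plus a JSON settings echo.

    ``results`` may carry ``differences`` (a DataFrame of per-diode records),
    ``gamma`` (a list of gamma-result summaries), and ``settings`` (criteria
    and thresholds, echoed verbatim for reproducibility).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {"settings": results.get("settings", {})}
    diffs = results.get("differences")
    if diffs is not None:
        diffs.to_csv(out / "differences.csv", index=False)
        summary["n_difference_records"] = int(len(diffs))
    else:
        (out / "differences.csv").write_text(
            "plan_id,diode_id,tps_dose_cGy,measured_dose_cGy,diff_cGy,"
            "pct_diff,passes_threshold\n"
        )
        summary["n_difference_records"] = 0
    gamma_rows = results.get("gamma", [])
    with open(out / "gamma_summary.csv", "w") as f:
        f.write("plan_id,dose_percent,dta_mm,threshold_percent,"
                "normalization,n_evaluated,pass_rate_percent\n")
        for row in gamma_rows:
            f.write(
                f"{row['plan_id']},{row['dose_percent']},{row['dta_mm']},"
                f"{row['threshold_percent']},{row['normalization']},"
                f"{row['n_evaluated']},{row['pass_rate_percent']}\n"
            )
    summary["n_gamma_rows"] = len(gamma_rows)
    for key in ("frequency", "statistics"):
        if key in results:
            summary[key] = results[key]
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))


def read_run_config(path: str | Path) -> dict:
    """Read a YAML run configuration file."""
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise FormatError("run configuration must be a YAML mapping")
    return cfg
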