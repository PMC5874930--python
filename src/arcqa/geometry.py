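"""Helical diode-array and ring-gantry beam geometry.

The detector is a cylindrical shell of PMMA carrying 1386 diodes laid out
on a helix, at a water-equivalent depth of 3.3 g cm^-2 (2.9 cm physical)
below the outer surface.  The treatment machine is a ring gantry with up to
three Co-60 heads mounted 120 degrees apart.

Conventions (fixed throughout the package):

* Right-handed coordinates with the isocenter at the origin and ``z`` along
  the cylinder axis; lengths in cm, dose in cGy, angles in degrees.
* Gantry angle 0 means the beam enters from the top, increasing clockwise
  when viewed from the couch foot.  In the axial plane a beam at gantry
  angle ``g`` has its source at ``(SAD*sin(g), SAD*cos(g), 0)``.
* Diode azimuths live in the same angular frame, normalized to [0, 360).
* The helix is left-handed in this frame: the azimuth increases with the
  diode index while ``z`` increases, with a fixed azimuthal step per diode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArrayConfig",
    "DiodeArrayGeometry",
    "BeamGeometry",
    "build_geometry",
    "relative_incidence_angle",
    "beam_source_position",
]

#: Number of full helix turns in the default 1386-diode build (66 diodes
#: per turn at 360/66 degrees apart, one turn per cm of axial travel).
_DEFAULT_TURNS = 21


class GeometryConfigError(ValueError):
    """Raised for non-physical geometry configuration values."""


@dataclass(frozen=True)
class ArrayConfig:
    """Parameters of the helical array build.

    Only the diode count and detector depth are device-quoted; the
    remaining dimensions are manufacturer-typical defaults and are
    configurable.
    """

    n_diodes: int = 1386
    detector_radius: float = 10.4       # cm, radius of the diode helix
    phantom_outer_radius: float = 13.3  # cm, outer PMMA surface
    phantom_length: float = 21.0        # cm, axial extent of the array
    helix_turns: int = _DEFAULT_TURNS   # full turns over phantom_length
    water_equivalent_depth: float = 3.3  # g cm^-2
    physical_depth: float = 2.9          # cm

    def validate(self) -> None:
        if self.n_diodes <= 0:
            raise GeometryConfigError("n_diodes must be positive")
        if self.detector_radius <= 0 or self.phantom_outer_radius <= 0:
            raise GeometryConfigError("radii must be positive")
        if self.phantom_length <= 0:
            raise GeometryConfigError("phantom_length must be positive")
        if self.helix_turns <= 0:
            raise GeometryConfigError("helix_turns must be positive")
        if self.detector_radius >= self.phantom_outer_radius:
            raise GeometryConfigError(
                "detector_radius must lie inside the phantom outer radius"
            )


@dataclass(frozen=True)
class DiodeArrayGeometry:
    """Diode coordinates of a helical cylindrical array.

    Attributes
    ----------
    diode_id : integer indices 0..N-1.
    z : axial position of each diode, cm (isocenter at 0).
    azimuth : angular position of each diode, degrees in [0, 360).
    """

    diode_id: np.ndarray
    z: np.ndarray
    azimuth: np.ndarray
    detector_radius: float
    water_equivalent_depth: float
    physical_depth: float
    phantom_outer_radius: float
    phantom_length: float
    name: str = "helical-1386"

    @property
    def n_diodes(self) -> int:
        return self.diode_id.size

    def positions(self) -> np.ndarray:
        """Cartesian diode positions, shape (N, 3), cm."""
        az = np.deg2rad(self.azimuth)
        r = self.detector_radius
        return np.column_stack([r * np.sin(az), r * np.cos(az), self.z])

    def to_dict(self) -> dict:
        """JSON-serializable layout: scalar metadata + diode table."""
        return {
            "name": self.name,
            "detector_radius_cm": self.detector_radius,
            "water_equivalent_depth_g_cm2": self.water_equivalent_depth,
            "physical_depth_cm": self.physical_depth,
            "phantom_outer_radius_cm": self.phantom_outer_radius,
            "phantom_length_cm": self.phantom_length,
            "diodes": [
                {"id": int(i), "z_cm": float(z), "azimuth_deg": float(a)}
                for i, z, a in zip(self.diode_id, self.z, self.azimuth)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiodeArrayGeometry":
        table = d["diodes"]
        return cls(
            diode_id=np.array([row["id"] for row in table], dtype=int),
            z=np.array([row["z_cm"] for row in table], dtype=float),
            azimuth=np.array([row["azimuth_deg"] for row in table], dtype=float),
            detector_radius=float(d["detector_radius_cm"]),
            water_equivalent_depth=float(d["water_equivalent_depth_g_cm2"]),
            physical_depth=float(d["physical_depth_cm"]),
            phantom_outer_radius=float(d["phantom_outer_radius_cm"]),
            phantom_length=float(d["phantom_length_cm"]),
            name=d.get("name", "custom"),
        )


@dataclass(frozen=True)
class BeamGeometry:
    """One treatment head's delivery parameters.

    ``gantry_angle`` refers to this head's own beam direction.  On the
    three-head ring the heads are mounted 120 degrees apart, so head k
    sits at head 1's angle + 120*(k-1) (mod 360); :meth:`from_head1_angle`
    constructs a head under that constraint.
    """

    head_id: int
    gantry_angle: float
    source_axis_distance: float = 105.0  # cm
    aperture: tuple[float, float] = (10.0, 10.0)  # (width, length) at iso, cm
    beam_on_time: float = 60.0  # s
    output_rate: float = 550.0  # cGy/min at isocenter distance, unattenuated

    def __post_init__(self):
        if not 1 <= self.head_id <= 3:
            raise GeometryConfigError("head_id must be 1, 2 or 3")
        if self.beam_on_time < 0:
            raise GeometryConfigError("beam_on_time must be >= 0")
        if self.source_axis_distance <= 0:
            raise GeometryConfigError("source_axis_distance must be positive")
        if min(self.aperture) <= 0:
            raise GeometryConfigError("aperture sides must be positive")
        object.__setattr__(self, "gantry_angle", float(self.gantry_angle) % 360.0)

    @classmethod
    def from_head1_angle(cls, head_id: int, head1_angle: float, **kwargs) -> "BeamGeometry":
        """Build head ``head_id`` given head 1's gantry angle (heads 120 deg apart)."""
        angle = (float(head1_angle) + 120.0 * (head_id - 1)) % 360.0
        return cls(head_id=head_id, gantry_angle=angle, **kwargs)

    @property
    def equivalent_square(self) -> float:
        """Equivalent-square side 2WL/(W+L) of the rectangular aperture, cm."""
        w, l = self.aperture
        return 2.0 * w * l / (w + l)


def build_geometry(config: ArrayConfig | None = None) -> DiodeArrayGeometry:
    """Construct the helical diode array from a configuration.

    Diode i sits at ``z = -L/2 + i * L/(N-1)`` and azimuth
    ``(i * 360 * turns / N) mod 360``, i.e. the helix advances a constant
    azimuthal step per diode while climbing the cylinder.  The build is
    deterministic: equal configs give field-by-field equal geometries.
    """
    config = config or ArrayConfig()
    config.validate()
    n = config.n_diodes
    ids = np.arange(n)
    if n == 1:
        z = np.zeros(1)
    else:
        z = -config.phantom_length / 2.0 + ids * (config.phantom_length / (n - 1))
    azimuth = (ids * (360.0 * config.helix_turns / n)) % 360.0
    return DiodeArrayGeometry(
        diode_id=ids,
        z=z,
        azimuth=azimuth,
        detector_radius=config.detector_radius,
        water_equivalent_depth=config.water_equivalent_depth,
        physical_depth=config.physical_depth,
        phantom_outer_radius=config.phantom_outer_radius,
        phantom_length=config.phantom_length,
        name=f"helical-{n}",
    )


def relative_incidence_angle(
    geometry: DiodeArrayGeometry,
    diode_id: int | np.ndarray,
    gantry_angle: float,
) -> float | np.ndarray:
    """Angle between the beam direction and the outward normal at a diode.

    0 means the beam enters directly over the diode (entry side); 180 means
    the diode sits on the exit side.  Result normalized to [0, 360).
    Because the gantry and azimuth share one angular frame, this reduces to
    ``(gantry_angle - azimuth) mod 360``.
    """
    diode_id = np.asarray(diode_id)
    if np.any(diode_id < 0) or np.any(diode_id >= geometry.n_diodes):
        raise KeyError(f"unknown diode_id in {diode_id!r}")
    az = geometry.azimuth[diode_id]
    out = (float(gantry_angle) - az) % 360.0
    if out.ndim == 0:
        return float(out)
    return out


def beam_source_position(beam: BeamGeometry) -> np.ndarray:
    """Cartesian source position of a beam, cm (z = 0 ring plane)."""
    g = np.deg2rad(beam.gantry_angle)
    sad = beam.source_axis_distance
    return np.array([sad * np.sin(g), sad * np.cos(g), 0.0])
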