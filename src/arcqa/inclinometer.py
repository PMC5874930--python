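"""Virtual inclinometer: recover the incident beam angle from the spatial
distribution of diode signals in one 50-ms measurement frame.

The beam entry point receives the highest dose (shortest path through the
phantom, closest to the source), so the azimuthal centroid of the
strongest diode signals points back at the gantry angle.  The estimate is
a circular mean of diode azimuths under soft-tapered weights
``max(increment - c * frame_max, 0)``: a hard membership cut would make
the cluster composition jump as the beam sweeps past the discrete diode
lattice, while the taper fades edge diodes in and out continuously and
keeps the centroid smooth in the true angle.  The estimate is
cross-checked against the exit-side signal cluster expected 180 degrees
away.

The method is only defined for single-beam frames: with two or three
simultaneous beams the signal forms multiple entry clusters, the circular
distribution loses coherence, and the frame is flagged ``ambiguous``
rather than guessed at.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import DiodeArrayGeometry
from .measurement import ConsistencyError, FrameSeries

__all__ = ["FrameAngleEstimate", "estimate_frame_angle", "estimate_angles",
           "angle_summary", "circular_error"]

#: frame total (cGy) below which a frame is considered beam-off
EMPTY_THRESHOLD_CGY = 1e-4
#: fraction of the frame maximum where the entry-cluster weight taper
#: reaches zero
TOP_FRACTION = 0.3
#: minimum circular resultant length of the entry cluster for a coherent,
#: single-beam signal
RESULTANT_MIN = 0.5
#: tolerated deviation (degrees) of the exit cluster from entry + 180
EXIT_TOLERANCE_DEG = 20.0
#: half-width (degrees) of the azimuthal window searched for the exit cluster
EXIT_WINDOW_DEG = 45.0


@dataclass(frozen=True)
class FrameAngleEstimate:
    """Angle estimate for one frame; ``angle`` is defined iff status is ok."""

    frame_index: int
    angle: float | None
    status: str  # "ok" | "empty" | "ambiguous"

    def __post_init__(self):
        if (self.angle is not None) != (self.status == "ok"):
            raise ValueError("angle must be defined exactly when status is 'ok'")


def circular_error(a: float, b: float) -> float:
    """Absolute angular difference in degrees, wrapped to [0, 180]."""
    d = abs((a - b) % 360.0)
    return min(d, 360.0 - d)


def _circular_mean(azimuth_deg: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Weighted circular mean (degrees in [0,360)) and resultant length."""
    rad = np.deg2rad(azimuth_deg)
    c = float(np.sum(weights * np.cos(rad)))
    s = float(np.sum(weights * np.sin(rad)))
    w = float(np.sum(weights))
    mean = float(np.degrees(np.arctan2(s, c))) % 360.0
    resultant = float(np.hypot(c, s) / w) if w > 0 else 0.0
    return mean, resultant


def estimate_frame_angle(
    frame: np.ndarray,
    geometry: DiodeArrayGeometry,
    frame_index: int = 0,
    empty_threshold: float = EMPTY_THRESHOLD_CGY,
    top_fraction: float = TOP_FRACTION,
    resultant_min: float = RESULTANT_MIN,
    exit_tolerance: float = EXIT_TOLERANCE_DEG,
) -> FrameAngleEstimate:
    """Estimate the gantry angle of a single-beam frame.

    Scale-free apart from the absolute beam-off threshold: the entry
    cluster is weighted relative to the frame maximum and the ambiguity
    checks use the normalized circular resultant, so multiplying the frame
    by any c > 0 (above threshold) changes nothing.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size != geometry.n_diodes:
        raise ConsistencyError(
            f"frame has {frame.size} entries, geometry {geometry.n_diodes} diodes"
        )
    if float(frame.sum()) < empty_threshold:
        return FrameAngleEstimate(frame_index, None, "empty")

    weights = np.clip(frame - top_fraction * float(frame.max()), 0.0, None)
    mask = weights > 0
    entry, resultant = _circular_mean(geometry.azimuth[mask], weights[mask])
    if resultant < resultant_min:
        return FrameAngleEstimate(frame_index, None, "ambiguous")

    # exit-side cross-check: the attenuated far-side cluster must sit near
    # entry + 180; a displaced or missing exit cluster means the entry
    # centroid cannot be trusted (overlapping beams, oblique artifacts)
    exit_expected = (entry + 180.0) % 360.0
    delta = np.abs((geometry.azimuth - exit_expected + 180.0) % 360.0 - 180.0)
    exit_mask = delta <= EXIT_WINDOW_DEG
    if not np.any(frame[exit_mask] > 0):
        return FrameAngleEstimate(frame_index, None, "ambiguous")
    exit_mean, _ = _circular_mean(geometry.azimuth[exit_mask], frame[exit_mask])
    if circular_error(exit_mean, exit_expected) > exit_tolerance:
        return FrameAngleEstimate(frame_index, None, "ambiguous")

    return FrameAngleEstimate(frame_index, entry, "ok")


def estimate_angles(
    series: FrameSeries,
    geometry: DiodeArrayGeometry,
    **kwargs,
) -> list[FrameAngleEstimate]:
    """Per-frame angle estimates for a whole series."""
    return [
        estimate_frame_angle(series.frames[i], geometry, frame_index=i, **kwargs)
        for i in range(series.n_frames)
    ]


def angle_summary(estimates: Sequence[FrameAngleEstimate]) -> dict:
    """Fractions of ok / empty / ambiguous frames in a series."""
    n = max(len(estimates), 1)
    counts = {"ok": 0, "empty": 0, "ambiguous": 0}
    for e in estimates:
        counts[e.status] += 1
    return {
        "n_frames": len(estimates),
        **{f"fraction_{k}": v / n for k, v in counts.items()},
    }
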