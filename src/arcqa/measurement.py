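"""In-memory containers for diode-array measurements.

A measurement is a vector of per-diode accumulated doses (cGy), optionally
backed by the 50-ms frame series it was accumulated from.  Frames carry the
per-diode dose increments of each measurement interval plus the set of
treatment heads active during that interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameSeries", "DiodeMeasurementSet", "ConsistencyError"]

#: Relative tolerance for the frame-sum vs. totals internal-consistency rule.
FRAME_TOTAL_RTOL = 1e-9


class ConsistencyError(ValueError):
    """Raised when measurement pieces disagree (counts, alignment, geometry)."""


@dataclass
class FrameSeries:
    """Per-interval dose increments.

    Attributes
    ----------
    frame_duration_ms : duration of one measurement interval (default 50 ms).
    frames : array (n_frames, n_diodes) of dose increments, cGy, all >= 0.
    active_beams : per-frame tuple of head ids contributing to that frame.
    """

    frames: np.ndarray
    frame_duration_ms: float = 50.0
    active_beams: list[tuple[int, ...]] = field(default_factory=list)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2:
            raise ConsistencyError("frames must be a 2D (n_frames, n_diodes) array")
        if self.frame_duration_ms <= 0:
            raise ConsistencyError("frame_duration_ms must be positive")
        if not np.all(np.isfinite(self.frames)) or np.any(self.frames < 0):
            raise ConsistencyError("frame increments must be finite and >= 0")
        if not self.active_beams:
            self.active_beams = [()] * self.n_frames
        if len(self.active_beams) != self.n_frames:
            raise ConsistencyError("active_beams length must match n_frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_diodes(self) -> int:
        return self.frames.shape[1]

    def totals(self) -> np.ndarray:
        """Per-diode sum over frames, cGy."""
        return self.frames.sum(axis=0)


@dataclass
class DiodeMeasurementSet:
    """Per-diode accumulated dose, raw or corrected.

    ``method`` labels how the totals were obtained: ``"raw"`` for an
    uncorrected accumulation, ``"weighted"`` for the dose-fraction-weighted
    correction, ``"framewise"`` for the per-interval correction.
    """

    totals: np.ndarray
    geometry_name: str = "helical-1386"
    plan_id: str = ""
    corrected: bool = False
    method: str = "raw"
    frames: FrameSeries | None = None
    #: set when a file's frame block disagreed with its totals column
    frame_total_mismatch: bool = False

    def __post_init__(self):
        self.totals = np.asarray(self.totals, dtype=float)
        if self.totals.ndim != 1:
            raise ConsistencyError("totals must be a 1D per-diode array")
        if not np.all(np.isfinite(self.totals)) or np.any(self.totals < 0):
            raise ConsistencyError("totals must be finite and >= 0")
        if self.frames is not None and self.frames.n_diodes != self.n_diodes:
            raise ConsistencyError(
                f"frame series has {self.frames.n_diodes} diodes, "
                f"totals have {self.n_diodes}"
            )

    @property
    def n_diodes(self) -> int:
        return self.totals.size

    def check_frame_totals(self, rtol: float = FRAME_TOTAL_RTOL) -> bool:
        """True when the frame sums match the totals within ``rtol``."""
        if self.frames is None:
            return True
        scale = max(float(self.totals.max(initial=0.0)), 1e-300)
        return bool(
            np.max(np.abs(self.frames.totals() - self.totals)) <= rtol * scale
        )
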