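"""Ion-chamber dose-to-water in a PMMA phantom, with uncertainty budget.

A calibrated chamber reading taken inside the PMMA cylinder is converted
to the absorbed dose to water that a water-phantom TG-51 measurement
would report, through the calibration coefficient, the standard influence
corrections, and two medium-conversion constants: the water/PMMA dose
ratio (Monte Carlo value 0.986 for Co-60) and the water/PMMA mean
restricted mass collision stopping-power ratio (0.973).  For Co-60 the
stopping-power ratio does not vary with depth at or beyond d_max, so no
depth-dependent term appears.

In the simplified form, only the electrometer and temperature-pressure
corrections are applied:

    D_w = M_raw * P_elec * P_TP * N_Dw * (D_w/D_PMMA) * (L/rho)_PMMA^w

Polarity, recombination and magnetic-field factors default to exactly 1
and are never applied silently; their expected ranges belong in the
uncertainty budget instead.  Budget components at k = 1 combine in
quadrature; rectangular distributions of half-width M contribute M/sqrt(3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ChamberReading",
    "DosimetryConstants",
    "UncertaintyBudget",
    "BudgetComponent",
    "compute_ptp",
    "chamber_dose_to_water",
    "rectangular_to_standard",
    "combine_budget",
    "CHAMBER_BUDGET",
    "COMPARISON_BUDGET_EXTRA",
]

#: reference calibration conditions: 22 C and 101.33 kPa
_T_REF_K = 295.2
_P_REF_KPA = 101.33


class DosimetryConfigError(ValueError):
    """Raised for missing or non-physical dosimetry inputs."""


def compute_ptp(temperature_c: float, pressure_kpa: float) -> float:
    """Temperature-pressure correction (273.2 + T)/295.2 * 101.33/P."""
    if not -50.0 < temperature_c < 100.0:
        raise DosimetryConfigError(f"non-physical temperature {temperature_c} C")
    if not 50.0 < pressure_kpa < 150.0:
        raise DosimetryConfigError(f"non-physical pressure {pressure_kpa} kPa")
    return (273.2 + temperature_c) / _T_REF_K * _P_REF_KPA / pressure_kpa


@dataclass(frozen=True)
class ChamberReading:
    """One chamber reading with its influence-correction values.

    Factors defaulting to exactly 1 (polarity, recombination, magnetic
    field) are *unapplied*; setting them requires an explicit value.
    """

    m_raw_nc: float
    temperature_c: float = 22.0
    pressure_kpa: float = 101.33
    p_elec: float = 1.0
    p_pol: float = 1.0
    p_ion: float = 1.0
    p_mf: float = 1.0
    physical_depth_cm: float = 2.9
    water_equivalent_depth: float = 3.3  # g cm^-2
    location_label: str = ""

    def __post_init__(self):
        if self.m_raw_nc < 0:
            raise DosimetryConfigError("m_raw_nc must be >= 0")
        if self.pressure_kpa <= 0:
            raise DosimetryConfigError("pressure must be positive")


@dataclass(frozen=True)
class DosimetryConstants:
    """Calibration coefficient and conversion constants.

    ``dose_ratio_w_pmma`` and ``stopping_power_ratio_w_pmma`` are the
    published Co-60 values for PMMA; ``k_q`` is 1.000 by definition for a
    Co-60 calibration and ``p_wall_ratio`` 1.000 for this chamber family.
    """

    n_dw_co60: float  # cGy / nC
    k_q: float = 1.000
    dose_ratio_w_pmma: float = 0.986
    stopping_power_ratio_w_pmma: float = 0.973
    p_wall_ratio: float = 1.000

    def __post_init__(self):
        for name in ("n_dw_co60", "k_q", "dose_ratio_w_pmma",
                     "stopping_power_ratio_w_pmma", "p_wall_ratio"):
            if getattr(self, name) <= 0:
                raise DosimetryConfigError(f"{name} must be strictly positive")


def chamber_dose_to_water(
    reading: ChamberReading,
    constants: DosimetryConstants,
    mode: Literal["full", "simplified"] = "simplified",
) -> float:
    """Absorbed dose to water (cGy) from a chamber reading in PMMA.

    ``simplified`` applies exactly M_raw * P_elec * P_TP * N * 0.986 * 0.973;
    ``full`` additionally multiplies P_pol, P_ion, P_MF, k_Q and the
    P_wall ratio, so the two modes coincide when those sit at their
    unapplied defaults of 1.  Linear in M_raw.
    """
    if mode not in ("full", "simplified"):
        raise DosimetryConfigError(f"unknown mode {mode!r}")
    ptp = compute_ptp(reading.temperature_c, reading.pressure_kpa)
    dose = (
        reading.m_raw_nc
        * reading.p_elec
        * ptp
        * constants.n_dw_co60
        * constants.dose_ratio_w_pmma
        * constants.stopping_power_ratio_w_pmma
    )
    if mode == "full":
        dose *= (
            reading.p_pol
            * reading.p_ion
            * reading.p_mf
            * constants.k_q
            * constants.p_wall_ratio
        )
    return dose


def rectangular_to_standard(half_width_percent: float) -> float:
    """Standard (k=1) uncertainty of a rectangular distribution: M/sqrt(3)."""
    if half_width_percent < 0:
        raise DosimetryConfigError("half-width must be >= 0")
    return half_width_percent / math.sqrt(3.0)


@dataclass(frozen=True)
class BudgetComponent:
    label: str
    value_percent: float  # at k = 1
    distribution: str = "normal"  # or "rectangular(M=x%)"
    comment: str = ""

    def __post_init__(self):
        if self.value_percent < 0:
            raise DosimetryConfigError("uncertainty components must be >= 0")


@dataclass
class UncertaintyBudget:
    """A list of k=1 components combined in quadrature.

    Components carry their printed (already-rounded) values; budgets can
    nest, so a total of one budget becomes a component of the next.
    """

    components: list[BudgetComponent] = field(default_factory=list)

    def values(self) -> np.ndarray:
        return np.array([c.value_percent for c in self.components])

    def extended(self, extra: Sequence[BudgetComponent]) -> "UncertaintyBudget":
        return UncertaintyBudget(components=list(self.components) + list(extra))


def combine_budget(budget: UncertaintyBudget, k: float = 1.0) -> float:
    """Expanded uncertainty: k * sqrt(sum of squared k=1 components), %."""
    if not budget.components:
        raise DosimetryConfigError("budget must carry at least one component")
    return float(k * math.sqrt(float(np.sum(budget.values() ** 2))))


#: The chamber-measurement budget: thirteen k=1 components.  The
#: volume-averaging row's printed 0.8% is carried as printed even though a
#: rectangular M=2% would imply 1.15%; printed component values are
#: combined as-is and the rectangular helper serves new budgets only.
CHAMBER_BUDGET = UncertaintyBudget(components=[
    BudgetComponent("Measurement repeatability", 0.5),
    BudgetComponent("P_pol", 0.3),
    BudgetComponent("P_ion", 0.3, "rectangular(M=0.5%)"),
    BudgetComponent("P_TP", 0.1),
    BudgetComponent("P_elec", 0.1),
    BudgetComponent("P_MF", 1.0),
    BudgetComponent("N_Dw_Co60", 0.7),
    BudgetComponent("k_Q", 0.5),
    BudgetComponent("Small-field effects", 2.0),
    BudgetComponent("Chamber position", 0.5),
    BudgetComponent("Chamber volume averaging", 0.8, "rectangular(M=2%)"),
    BudgetComponent("Stopping-power ratio w/PMMA", 1.4),
    BudgetComponent("Dose ratio w/PMMA", 0.2),
])

#: Additional k=1 components entering chamber-vs-array dose comparisons.
COMPARISON_BUDGET_EXTRA = [
    BudgetComponent("TPS dose calculation", 1.0),
    BudgetComponent("Diode accuracy/consistency", 0.8),
    BudgetComponent("Beam-weight extraction", 2.0),
]
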