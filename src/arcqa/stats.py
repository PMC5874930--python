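"""Frequency and cumulative-difference analysis, pass-rate summaries,
and the t-tests used to compare measurement campaigns.

Percent differences are local (relative to the reference dose at each
diode); the inclusion threshold is global (a percentage of the maximum
reference dose in the plan).  The 50% cumulative-frequency point of the
absolute differences (p50) is the empirical-CDF crossing: the smallest
difference value at which the cumulative frequency reaches 50%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gamma import GammaResult
from .measurement import ConsistencyError, DiodeMeasurementSet

__all__ = [
    "DifferenceTable",
    "FrequencySummary",
    "TestResult",
    "difference_records",
    "frequency_analysis",
    "summarize_pass_rates",
    "t_test_two_sample_one_sided",
    "t_test_paired_two_sided",
    "compare_difference_distributions",
]

_COLUMNS = [
    "plan_id", "diode_id", "tps_dose_cGy", "measured_dose_cGy",
    "diff_cGy", "pct_diff", "passes_threshold",
]


@dataclass
class DifferenceTable:
    """Per-diode measured-vs-reference records across one or more plans."""

    records: pd.DataFrame

    def __post_init__(self):
        missing = set(_COLUMNS) - set(self.records.columns)
        if missing:
            raise ConsistencyError(f"difference table missing columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.records)

    def thresholded(self) -> pd.DataFrame:
        return self.records[self.records.passes_threshold]

    @classmethod
    def concat(cls, tables: Sequence["DifferenceTable"]) -> "DifferenceTable":
        return cls(pd.concat([t.records for t in tables], ignore_index=True))


def difference_records(
    tps_at_diodes: np.ndarray,
    measured: DiodeMeasurementSet | np.ndarray,
    threshold_percent: float = 10.0,
    plan_id: str | None = None,
) -> DifferenceTable:
    """Signed measured - reference differences for one plan.

    ``passes_threshold`` marks diodes whose reference dose reaches
    ``threshold_percent`` of the plan's maximum reference dose; percent
    differences are left undefined (NaN) where the reference dose is 0.
    """
    tps = np.asarray(tps_at_diodes, dtype=float)
    if isinstance(measured, DiodeMeasurementSet):
        m = measured.totals
        plan_id = measured.plan_id if plan_id is None else plan_id
    else:
        m = np.asarray(measured, dtype=float)
    if tps.shape != m.shape:
        raise ConsistencyError("reference and measured vectors must align")
    diff = m - tps
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(tps > 0, 100.0 * diff / tps, np.nan)
    dmax = float(tps.max()) if tps.size else 0.0
    passes = tps >= threshold_percent / 100.0 * dmax
    return DifferenceTable(pd.DataFrame({
        "plan_id": plan_id or "",
        "diode_id": np.arange(tps.size),
        "tps_dose_cGy": tps,
        "measured_dose_cGy": m,
        "diff_cGy": diff,
        "pct_diff": pct,
        "passes_threshold": passes,
    }))


@dataclass
class FrequencySummary:
    """Histograms plus the cumulative curve over absolute differences."""

    n_records: int
    signed_cgy_edges: np.ndarray
    signed_cgy_counts: np.ndarray
    signed_pct_edges: np.ndarray
    signed_pct_counts: np.ndarray
    abs_cgy_sorted: np.ndarray          # support of the empirical CDF
    cumulative_percent: np.ndarray      # non-decreasing, ends at 100
    p50_abs_diff_cgy: float
    p50_abs_pct: float
    empty: bool = False


def _p50(abs_values: np.ndarray) -> float:
    """Smallest value at which the cumulative frequency reaches 50%."""
    v = np.sort(abs_values)
    k = int(np.ceil(0.5 * v.size)) - 1
    return float(v[k])


def frequency_analysis(
    table: DifferenceTable,
    bin_width_cgy: float = 1.0,
    bin_width_pct: float = 1.0,
    thresholded: bool = True,
) -> FrequencySummary:
    """Histogram and cumulative-frequency summary of a difference table."""
    rec = table.thresholded() if thresholded else table.records
    if len(rec) == 0:
        return FrequencySummary(
            n_records=0,
            signed_cgy_edges=np.array([]), signed_cgy_counts=np.array([]),
            signed_pct_edges=np.array([]), signed_pct_counts=np.array([]),
            abs_cgy_sorted=np.array([]), cumulative_percent=np.array([]),
            p50_abs_diff_cgy=float("nan"), p50_abs_pct=float("nan"),
            empty=True,
        )
    diffs = rec.diff_cGy.to_numpy()
    pct = rec.pct_diff.to_numpy()
    pct_finite = pct[np.isfinite(pct)]

    def _edges(values: np.ndarray, width: float) -> np.ndarray:
        lo = np.floor(values.min() / width) * width
        hi = np.ceil(values.max() / width) * width
        if hi <= lo:
            hi = lo + width
        return np.arange(lo, hi + width / 2, width)

    cgy_edges = _edges(diffs, bin_width_cgy)
    cgy_counts, _ = np.histogram(diffs, bins=cgy_edges)
    if pct_finite.size:
        pct_edges = _edges(pct_finite, bin_width_pct)
        pct_counts, _ = np.histogram(pct_finite, bins=pct_edges)
    else:
        pct_edges, pct_counts = np.array([]), np.array([])

    abs_sorted = np.sort(np.abs(diffs))
    cumulative = 100.0 * np.arange(1, abs_sorted.size + 1) / abs_sorted.size
    return FrequencySummary(
        n_records=len(rec),
        signed_cgy_edges=cgy_edges, signed_cgy_counts=cgy_counts,
        signed_pct_edges=pct_edges, signed_pct_counts=pct_counts,
        abs_cgy_sorted=abs_sorted, cumulative_percent=cumulative,
        p50_abs_diff_cgy=_p50(np.abs(diffs)),
        p50_abs_pct=_p50(np.abs(pct_finite)) if pct_finite.size else float("nan"),
    )


def summarize_pass_rates(results: Sequence[GammaResult | float]) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation of pass rates, %.

    A singleton gives (rate, nan): the sample SD is undefined at n = 1.
    """
    if len(results) == 0:
        raise ConsistencyError("at least one gamma result required")
    rates = np.array([
        r.pass_rate if isinstance(r, GammaResult) else float(r) for r in results
    ])
    mean = float(rates.mean())
    sd = float(rates.std(ddof=1)) if rates.size > 1 else float("nan")
    return mean, sd


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    sidedness: str
    paired: bool
    degenerate: bool = False


def t_test_two_sample_one_sided(
    a: np.ndarray, b: np.ndarray, alternative: str = "greater"
) -> TestResult:
    """Welch two-sample t-test, one-sided.

    ``alternative="greater"`` tests mean(b) > mean(a).  Zero pooled
    variance flags the result degenerate instead of producing a p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConsistencyError("each sample needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        return TestResult(float("nan"), float("nan"), float("nan"),
                          f"one-sided ({alternative})", False, degenerate=True)
    res = sps.ttest_ind(b, a, equal_var=False, alternative=alternative)
    return TestResult(
        statistic=float(res.statistic), df=float(res.df),
        p_value=float(res.pvalue), sidedness=f"one-sided ({alternative})",
        paired=False,
    )


def t_test_paired_two_sided(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Paired t-test on b - a, two-sided; zero-variance differences flag
    the result degenerate."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ConsistencyError("paired samples need equal lengths, n >= 2")
    d = b - a
    if np.var(d, ddof=1) == 0:
        return TestResult(float("nan"), float(a.size - 1), float("nan"),
                          "two-sided", True, degenerate=True)
    res = sps.ttest_rel(b, a)
    return TestResult(
        statistic=float(res.statistic), df=float(a.size - 1),
        p_value=float(res.pvalue), sidedness="two-sided", paired=True,
    )


def compare_difference_distributions(
    set_a: DifferenceTable, set_b: DifferenceTable
) -> dict:
    """Side-by-side summary of two difference tables (no significance claim)."""
    out = {}
    for name, table in (("a", set_a), ("b", set_b)):
        rec = table.thresholded()
        if len(rec) == 0:
            raise ConsistencyError(f"difference table '{name}' is empty after threshold")
        out[name] = {
            "n": len(rec),
            "mean_diff_cgy": float(rec.diff_cGy.mean()),
            "p50_abs_diff_cgy": _p50(np.abs(rec.diff_cGy.to_numpy())),
        }
    out["p50_shift_cgy"] = out["b"]["p50_abs_diff_cgy"] - out["a"]["p50_abs_diff_cgy"]
    out["mean_shift_cgy"] = out["b"]["mean_diff_cgy"] - out["a"]["mean_diff_cgy"]
    return out
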