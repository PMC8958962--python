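"""Relative-difference statistics between comparison and baseline year.

Volume variables (distance, duration, runs) are compared per athlete-week:

    diff[a, w] = 100 * (comparison[a, w] - baseline[a, w]) / mean(baseline)

where ``mean(baseline)`` is a single scalar, the mean over all athlete-week
cells of the baseline matrix (zeros included).  The weekly athlete count is
compared analogously against the mean weekly count in the baseline year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .weekly import N_WEEKS, WeeklyMatrix

STRATIFY_KEYS = ("gender", "age_group", "country")


@dataclass
class DiffMatrix:
    """Athlete x 52 grid of relative differences, in percent."""

    variable: str
    values: pd.DataFrame
    baseline_mean: float

    def weekly_samples(self, week: int) -> np.ndarray:
        """Per-athlete differences for a 1-based week."""
        return self.values[week].to_numpy(dtype=float)

    def to_long_csv(self, path) -> None:
        long = self.values.rename_axis("athlete").reset_index().melt(
            id_vars="athlete", var_name="week", value_name="value"
        )
        long.sort_values(["athlete", "week"]).to_csv(path, index=False)


@dataclass
class CountDiffSeries:
    """52 weekly relative differences of the running-athlete count, percent."""

    values: np.ndarray
    baseline_mean_count: float

    def to_csv(self, path) -> None:
        pd.DataFrame({"week": range(1, N_WEEKS + 1), "value": self.values}).to_csv(
            path, index=False
        )


def percent_change(new: float, old: float) -> float:
    """Plain relative change 100 * (new - old) / old."""
    if old == 0:
        raise ZeroDivisionError("relative change undefined for zero baseline")
    return 100.0 * (new - old) / old


def volume_relative_difference(
    m_comparison: WeeklyMatrix, m_baseline: WeeklyMatrix
) -> DiffMatrix:
    """Per-athlete-week relative difference against the baseline overall mean."""
    if m_comparison.variable != m_baseline.variable:
        raise ValueError("matrices measure different variables")
    if not m_comparison.values.index.equals(m_baseline.values.index):
        raise ValueError("matrices must share the athlete set")
    baseline_mean = float(m_baseline.values.to_numpy(dtype=float).mean())
    if baseline_mean <= 0:
        raise ValueError("degenerate cohort: baseline overall mean is zero")
    values = 100.0 * (m_comparison.values - m_baseline.values) / baseline_mean
    return DiffMatrix(m_comparison.variable, values, baseline_mean)


def count_relative_difference(
    c_comparison: np.ndarray, c_baseline: np.ndarray
) -> CountDiffSeries:
    """Weekly athlete-count difference relative to the mean baseline count."""
    c_comparison = np.asarray(c_comparison, dtype=float)
    c_baseline = np.asarray(c_baseline, dtype=float)
    if c_comparison.shape != (N_WEEKS,) or c_baseline.shape != (N_WEEKS,):
        raise ValueError(f"count series must have length {N_WEEKS}")
    baseline_mean = float(c_baseline.mean())
    if baseline_mean <= 0:
        raise ValueError("degenerate baseline: mean athlete count is zero")
    values = 100.0 * (c_comparison - c_baseline) / baseline_mean
    return CountDiffSeries(values, baseline_mean)


def stratify(cohort: Cohort, by: str) -> dict[str, list[int]]:
    """Partition the cohort's athlete ids by a demographic key.

    Athletes with a missing country fall into an explicit ``"unknown"``
    stratum.  The strata partition the cohort exactly.
    """
    if by not in STRATIFY_KEYS:
        raise ValueError(f"stratification key must be one of {STRATIFY_KEYS}")
    strata: dict[str, list[int]] = {}
    for aid in cohort.athlete_ids:
        value = getattr(cohort.profiles[aid], by)
        if by == "country" and not value:
            value = "unknown"
        strata.setdefault(value, []).append(aid)
    return strata
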