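"""52-week analysis calendar and per-athlete weekly outcome variables.

The analysis year is cut into 52 consecutive blocks of 7 days anchored at
January 1; block 52 absorbs the leftover day(s), so it spans 8 days in a
365-day year and 9 days in a leap year.  Weekly outcome variables are

* ``distance`` — kilometers summed over the week,
* ``duration`` — minutes summed over the week,
* ``runs``     — number of days in the week with positive running volume,

with explicit zeros for weeks in which the athlete did not run.  The final
week is rescaled by 7/8 (or 7/9) so every week represents a 7-day rate.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort

N_WEEKS = 52

VOLUME_VARIABLES = ("distance", "duration", "runs")


@dataclass(frozen=True)
class WeekCalendar:
    """Partition of a calendar year into 52 contiguous week spans."""

    year: int
    starts: tuple[dt.date, ...]
    ends: tuple[dt.date, ...]  # inclusive

    def days_in_week(self, week: int) -> int:
        """Number of days in 1-based ``week``."""
        return (self.ends[week - 1] - self.starts[week - 1]).days + 1

    def week_of(self, date: dt.date) -> int:
        """1-based week containing ``date``."""
        if date.year != self.year:
            raise ValueError(f"{date} not in calendar year {self.year}")
        doy = date.timetuple().tm_yday
        return min((doy - 1) // 7, N_WEEKS - 1) + 1


def build_week_calendar(year: int) -> WeekCalendar:
    """52 consecutive 7-day blocks from January 1; week 52 takes the rest."""
    if year < 1583:
        raise ValueError("calendar requires a Gregorian year (>= 1583)")
    jan1 = dt.date(year, 1, 1)
    dec31 = dt.date(year, 12, 31)
    starts = [jan1 + dt.timedelta(days=7 * i) for i in range(N_WEEKS)]
    ends = [s + dt.timedelta(days=6) for s in starts[:-1]] + [dec31]
    return WeekCalendar(year, tuple(starts), tuple(ends))


@dataclass
class WeeklyMatrix:
    """Athlete x 52 grid of one weekly outcome variable.

    ``values`` is indexed by athlete id with integer columns 1..52; inactive
    weeks hold exact zeros.
    """

    variable: str
    values: pd.DataFrame
    year: int

    def __post_init__(self) -> None:
        if self.values.shape[1] != N_WEEKS:
            raise ValueError(f"weekly matrix must have {N_WEEKS} columns")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("weekly values must be non-negative")

    @property
    def athletes(self) -> np.ndarray:
        return self.values.index.to_numpy()

    def to_csv(self, path) -> None:
        self.values.rename_axis("athlete").to_csv(path)


def aggregate_weekly(
    daily: pd.DataFrame, calendar: WeekCalendar, cohort: Cohort
) -> dict[str, WeeklyMatrix]:
    """Aggregate per-athlete daily totals into weekly outcome matrices.

    ``daily`` has columns ``athlete, date, distance, duration`` (one row per
    active athlete-day).  Every cohort athlete gets a row, all-zero if they
    have no records.  Returns matrices for distance, duration and runs; the
    runs count is the number of active days (positive distance) in the week.
    """
    athletes = pd.Index(cohort.athlete_ids, name="athlete")
    daily = daily[daily["athlete"].isin(athletes)]
    frames: dict[str, pd.DataFrame] = {}

    if len(daily):
        dates = pd.to_datetime(daily["date"])
        if (dates.dt.year != calendar.year).any():
            bad = daily.loc[dates.dt.year != calendar.year].iloc[0]
            raise ValueError(
                f"activity for athlete {int(bad['athlete'])} dated {bad['date']} "
                f"outside calendar year {calendar.year}"
            )
        doy = dates.dt.dayofyear
        week = np.minimum((doy - 1) // 7, N_WEEKS - 1) + 1
        work = daily.assign(week=week, runs=(daily["distance"] > 0).astype(float))
        grouped = work.groupby(["athlete", "week"])[list(VOLUME_VARIABLES)].sum()
        for var in VOLUME_VARIABLES:
            frames[var] = grouped[var].unstack("week", fill_value=0.0)
    else:
        for var in VOLUME_VARIABLES:
            frames[var] = pd.DataFrame(index=pd.Index([], name="athlete"))

    out = {}
    for var, frame in frames.items():
        frame = frame.reindex(index=athletes, columns=range(1, N_WEEKS + 1), fill_value=0.0)
        out[var] = WeeklyMatrix(var, frame.astype(float), calendar.year)
    return out


def adjust_final_week(matrix: WeeklyMatrix, calendar: WeekCalendar) -> WeeklyMatrix:
    """Rescale week 52 by 7 / days-in-week-52 (7/8 for 2019, 7/9 for 2020)."""
    factor = 7.0 / calendar.days_in_week(N_WEEKS)
    values = matrix.values.copy()
    values[N_WEEKS] = values[N_WEEKS] * factor
    return WeeklyMatrix(matrix.variable, values, matrix.year)


def active_athletes_per_week(matrix: WeeklyMatrix) -> np.ndarray:
    """Per-week count of athletes with positive volume; length 52."""
    return (matrix.values.to_numpy() > 0).sum(axis=0).astype(float)


def weekly_pace(
    duration_matrix: WeeklyMatrix, distance_matrix: WeeklyMatrix
) -> pd.DataFrame:
    """Weekly average pace (min/km) = duration / distance.

    Weeks with zero distance are undefined and returned as NaN, never zero.
    """
    if not duration_matrix.values.index.equals(distance_matrix.values.index):
        raise ValueError("pace requires matrices over the same athletes")
    dur = duration_matrix.values.to_numpy(dtype=float)
    dist = distance_matrix.values.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pace = np.where(dist > 0, dur / np.where(dist > 0, dist, 1.0), np.nan)
    return pd.DataFrame(
        pace, index=duration_matrix.values.index, columns=duration_matrix.values.columns
    )
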