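"""Government COVID-19 response stringency index, aligned to the analysis weeks.

The index is a 0-100 composite of nine policy response metrics reported per
country and day.  For comparison against the weekly running series it is
averaged over the 52 analysis week spans and combined across countries as
a weighted mean, each country weighted by its number of athletes in the
cohort.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .weekly import N_WEEKS, WeekCalendar

logger = logging.getLogger(__name__)

COLUMNS = ("country", "date", "score")


def load_stringency(path: str | Path) -> pd.DataFrame:
    """Read and validate a country x day stringency CSV.

    Scores must lie in [0, 100]; each (country, day) pair may appear once.
    """
    frame = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"stringency file missing column(s): {', '.join(missing)}")
    frame = frame.loc[:, list(COLUMNS)].copy()
    frame["date"] = pd.to_datetime(frame["date"])
    frame["score"] = pd.to_numeric(frame["score"])
    bad = frame.index[(frame["score"] < 0) | (frame["score"] > 100)]
    if len(bad):
        raise ValueError(
            f"row {int(bad[0])}: stringency score outside [0, 100] "
            f"({frame.loc[bad[0], 'score']})"
        )
    if frame.duplicated(["country", "date"]).any():
        raise ValueError("duplicate (country, date) entries in stringency table")
    return frame


def write_stringency(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = table.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
    return path


def weekly_stringency(table: pd.DataFrame, calendar: WeekCalendar) -> pd.DataFrame:
    """Mean daily score per country per analysis week (country x 52)."""
    dates = pd.to_datetime(table["date"])
    if (dates.dt.year != calendar.year).any():
        raise ValueError(f"stringency dates outside calendar year {calendar.year}")
    doy = dates.dt.dayofyear
    week = np.minimum((doy - 1) // 7, N_WEEKS - 1) + 1
    weekly = (
        table.assign(week=week)
        .groupby(["country", "week"])["score"]
        .mean()
        .unstack("week")
        .reindex(columns=range(1, N_WEEKS + 1))
    )
    return weekly


def weighted_stringency(
    weekly: pd.DataFrame, athlete_counts: dict[str, int]
) -> np.ndarray:
    """Cross-country weekly average weighted by per-country athlete counts.

    Countries with athletes but no stringency data are dropped with a
    warning; the result is bounded each week by the per-week minimum and
    maximum across the weighted countries.
    """
    present = {c: n for c, n in athlete_counts.items() if c in weekly.index and n > 0}
    dropped = sorted(set(athlete_counts) - set(present))
    if dropped:
        logger.warning(
            "no stringency data for %d countr%s: %s",
            len(dropped),
            "y" if len(dropped) == 1 else "ies",
            ", ".join(map(str, dropped[:10])),
        )
    if not present:
        raise ValueError("zero total weight: no weighted country has stringency data")
    countries = sorted(present)
    weights = np.array([present[c] for c in countries], dtype=float)
    scores = weekly.loc[countries].to_numpy(dtype=float)
    return (scores * weights[:, None]).sum(axis=0) / weights.sum()
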