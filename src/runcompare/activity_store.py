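"""Data model and I/O for per-athlete running activity records.

An activity table holds one row per running bout (or per athlete-period
after resampling) with the eight-column schema used by the published
running datasets::

    datetime, athlete, distance, duration, gender, age_group, country, major

``distance`` is in kilometers, ``duration`` in minutes.  Files are named
``run_ww_<yyyy>_<f>`` where ``<f>`` is the sampling frequency: ``d`` (day),
``w`` (week) or ``m`` (month).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCHEMA_COLUMNS = (
    "datetime",
    "athlete",
    "distance",
    "duration",
    "gender",
    "age_group",
    "country",
    "major",
)

GENDERS = frozenset({"M", "F"})
AGE_GROUPS = ("18-34", "35-54", "55+")

FREQUENCIES = ("d", "w", "m")


class SchemaError(ValueError):
    """A mandatory column is missing or has the wrong type."""


class RecordValidationError(ValueError):
    """A row violates a field-level invariant; carries the row index."""

    def __init__(self, message: str, row: int):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass
class ActivityTable:
    """Validated collection of activity records for one calendar year.

    Parameters
    ----------
    frame
        DataFrame with the eight schema columns; ``datetime`` is held as
        timezone-naive ``datetime64[ns]`` calendar days.
    year
        The study year all record dates fall into.
    """

    frame: pd.DataFrame
    year: int = field(default=0)

    def __post_init__(self) -> None:
        self.frame = _validate_frame(self.frame)
        if not self.year:
            if len(self.frame):
                self.year = int(self.frame["datetime"].dt.year.mode().iloc[0])
        if len(self.frame):
            years = self.frame["datetime"].dt.year
            bad = self.frame.index[years != self.year]
            if len(bad):
                raise RecordValidationError(
                    f"date outside study year {self.year}", int(bad[0])
                )
        _check_demographic_consistency(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def athletes(self) -> np.ndarray:
        """Sorted unique athlete ids present in the table."""
        return np.sort(self.frame["athlete"].unique())


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SCHEMA_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    extra = [c for c in frame.columns if c not in SCHEMA_COLUMNS]
    if extra:
        logger.warning("ignoring unknown columns: %s", ", ".join(extra))
    frame = frame.loc[:, list(SCHEMA_COLUMNS)].reset_index(drop=True)

    dates = pd.to_datetime(frame["datetime"], errors="coerce", format="mixed")
    bad = frame.index[dates.isna()]
    if len(bad):
        raise RecordValidationError("unparseable date", int(bad[0]))
    frame["datetime"] = dates.dt.normalize()

    for col in ("distance", "duration"):
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[vals.isna() | (vals < 0)]
        if len(bad):
            raise RecordValidationError(f"negative or non-numeric {col}", int(bad[0]))
        frame[col] = vals.astype(float)

    frame["athlete"] = pd.to_numeric(frame["athlete"], errors="raise").astype(np.int64)
    if (frame["athlete"] < 0).any():
        row = int(frame.index[frame["athlete"] < 0][0])
        raise RecordValidationError("negative athlete id", row)

    bad = frame.index[~frame["gender"].isin(GENDERS)]
    if len(bad):
        raise RecordValidationError("gender must be 'M' or 'F'", int(bad[0]))
    bad = frame.index[~frame["age_group"].isin(AGE_GROUPS)]
    if len(bad):
        raise RecordValidationError(
            f"age_group must be one of {AGE_GROUPS}", int(bad[0])
        )
    frame["country"] = frame["country"].astype(str)
    frame["major"] = frame["major"].astype(str)
    return frame


def _check_demographic_consistency(frame: pd.DataFrame) -> None:
    if not len(frame):
        return
    per_athlete = frame.groupby("athlete")[["gender", "age_group", "country"]].nunique()
    inconsistent = per_athlete.index[(per_athlete > 1).any(axis=1)]
    if len(inconsistent):
        raise SchemaError(
            f"athlete {int(inconsistent[0])} has inconsistent demographic fields"
        )


def file_name(year: int, frequency: str, fmt: str = "parquet") -> str:
    """Return the conventional dataset file name ``run_ww_<yyyy>_<f>``."""
    if frequency not in FREQUENCIES:
        raise ValueError(f"frequency must be one of {FREQUENCIES}")
    ext = "parquet" if fmt == "parquet" else "csv"
    return f"run_ww_{year}_{frequency}.{ext}"


def read_activities(path: str | Path, fmt: str | None = None) -> ActivityTable:
    """Read an activity file (Parquet or CSV) into a validated table.

    ``fmt`` is inferred from the file suffix when not given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "parquet"
    if fmt == "csv":
        frame = pd.read_csv(path)
    else:
        frame = pd.read_parquet(path)
    return ActivityTable(frame)


def write_activities(
    table: ActivityTable,
    directory: str | Path,
    frequency: str = "d",
    fmt: str = "parquet",
) -> Path:
    """Write a table resampled to ``frequency`` under the naming convention.

    Rows are aggregated to one per (athlete, period): distance and duration
    are summed and ``datetime`` is the first day of the period.  A table
    already at the requested granularity round-trips exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = directory / file_name(table.year, frequency, fmt)

    frame = table.frame
    if len(frame):
        if frequency == "d":
            key = frame["datetime"]
        else:
            code = {"w": "W", "m": "M"}[frequency]
            key = frame["datetime"].dt.to_period(code).dt.start_time
            # a calendar week can start in the previous year; keep the file
            # within its study year
            key = key.clip(lower=pd.Timestamp(table.year, 1, 1))
        demo = frame.groupby("athlete")[
            ["gender", "age_group", "country", "major"]
        ].first()
        agg = (
            frame.assign(datetime=key)
            .groupby(["athlete", "datetime"], as_index=False)[["distance", "duration"]]
            .sum()
        )
        agg = agg.join(demo, on="athlete")
        agg = agg.loc[:, list(SCHEMA_COLUMNS)]
    else:
        agg = frame.copy()

    if fmt == "csv":
        out_frame = agg.copy()
        if len(out_frame):
            out_frame["datetime"] = out_frame["datetime"].dt.strftime("%Y-%m-%d")
        out_frame.to_csv(out, index=False)
    else:
        agg.to_parquet(out, index=False)
    return out


def daily_totals(table: ActivityTable) -> pd.DataFrame:
    """Sum multiple same-day bouts into per-athlete daily totals.

    Returns a frame with columns ``athlete, date, distance, duration``, one
    row per (athlete, day) that has at least one recorded bout.  Total
    distance and duration are conserved exactly.
    """
    frame = table.frame
    out = (
        frame.assign(date=frame["datetime"])
        .groupby(["athlete", "date"], as_index=False)[["distance", "duration"]]
        .sum()
        .sort_values(["athlete", "date"], ignore_index=True)
    )
    return out
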