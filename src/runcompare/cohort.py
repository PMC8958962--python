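"""Within-subject cohort selection and per-athlete demographics.

The comparison is within-subject: every athlete is measured against their
own baseline year, so the cohort is fixed to the athletes with at least one
run in the baseline year.  Athletes who stop running in the comparison year
stay in the cohort (they contribute zero weeks); athletes who only appear
in the comparison year are excluded.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .activity_store import AGE_GROUPS, ActivityTable

logger = logging.getLogger(__name__)

#: Midpoint ages used when shifting a reported age interval forward in time.
#: The open-ended top group is given midpoint 60, which keeps any athlete
#: already in it there under forward shifts.
_AGE_MIDPOINTS = {"18-34": 26.0, "35-54": 44.5, "55+": 60.0}

MISSING_COUNTRY = ""


@dataclass(frozen=True)
class AthleteProfile:
    """One athlete's demographics, resolved to the reference year."""

    athlete_id: int
    gender: str
    age_group: str
    country: str
    majors: tuple[str, ...] = ()


@dataclass
class Cohort:
    """The fixed set of athletes compared across the two study years."""

    profiles: dict[int, AthleteProfile]
    reference_year: int
    comparison_year: int

    def __len__(self) -> int:
        return len(self.profiles)

    @property
    def athlete_ids(self) -> list[int]:
        return sorted(self.profiles)


def select_within_subject_cohort(
    baseline: ActivityTable, comparison: ActivityTable
) -> Cohort:
    """Keep exactly the athletes with >= 1 record in the baseline year.

    New athletes appearing only in the comparison year are dropped; baseline
    athletes inactive in the comparison year are retained and later
    contribute all-zero comparison weeks.
    """
    if not len(baseline.frame):
        logger.warning("empty baseline table: cohort is empty")
        return Cohort({}, baseline.year, comparison.year)

    frame = baseline.frame
    demo = frame.groupby("athlete")[["gender", "age_group", "country", "major"]].first()
    profiles = {
        int(aid): AthleteProfile(
            athlete_id=int(aid),
            gender=row.gender,
            age_group=row.age_group,
            country=row.country,
            majors=tuple(m for m in str(row.major).split(";") if m),
        )
        for aid, row in demo.iterrows()
    }
    return Cohort(profiles, baseline.year, comparison.year)


def update_age_group(reported_group: str, marathon_year: int, target_year: int) -> str:
    """Shift a reported age interval to a later reference year.

    The athlete's age at the marathon is estimated as the midpoint of the
    reported interval; the year gap is added and the result is floored to
    whole years before mapping back into the three analysis groups.
    """
    if marathon_year > target_year:
        raise ValueError("marathon_year must not exceed target_year")
    if reported_group not in _AGE_MIDPOINTS:
        raise ValueError(f"unknown age group {reported_group!r}")
    age = int(_AGE_MIDPOINTS[reported_group] + (target_year - marathon_year))
    if age < 35:
        return "18-34"
    if age < 55:
        return "35-54"
    return "55+"


def infer_country(country_labels: list[str]) -> str:
    """Modal country label, ties broken lexicographically.

    An empty list yields the missing-country marker (empty string).
    """
    labels = [c for c in country_labels if c]
    if not labels:
        return MISSING_COUNTRY
    counts = Counter(labels)
    top = max(counts.values())
    return min(label for label, n in counts.items() if n == top)


def demographic_summary(cohort: Cohort) -> pd.DataFrame:
    """Cohort composition by gender, age group and country.

    Returns a frame with columns ``variable, stratum, count, proportion``;
    proportions sum to 1 within each variable.
    """
    if not len(cohort):
        raise ValueError("cohort is empty")
    rows = []
    frame = pd.DataFrame(
        {
            "gender": [p.gender for p in cohort.profiles.values()],
            "age_group": [p.age_group for p in cohort.profiles.values()],
            "country": [p.country or "unknown" for p in cohort.profiles.values()],
        }
    )
    n = len(frame)
    for variable in ("gender", "age_group", "country"):
        counts = frame[variable].value_counts().sort_index()
        if variable == "age_group":
            counts = counts.reindex(
                [g for g in AGE_GROUPS if g in counts.index]
            )
        for stratum, count in counts.items():
            rows.append(
                {
                    "variable": variable,
                    "stratum": stratum,
                    "count": int(count),
                    "proportion": count / n,
                }
            )
    return pd.DataFrame(rows)


def write_demographics(cohort: Cohort, path: str | Path) -> Path:
    path = Path(path)
    demographic_summary(cohort).to_csv(path, index=False)
    return path
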