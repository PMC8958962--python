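"""Synthetic two-year running cohorts with a known injected effect.

The generator emulates the statistical structure the analysis assumes:

* demographics matching the study cohort (76% male; 34/59/7% across the
  18-34 / 35-54 / 55+ age groups; a ten-country-dominated country mix);
* zero-inflated weekly volumes — each athlete runs in a given week with
  probability ~0.75, contributing exact zeros otherwise;
* long-tailed positive volumes — per-run distance is lognormal with an
  athlete-level multiplicative random effect, calibrated so the cohort
  mean weekly distance is ~29 km and mean runs per week ~2.46;
* an injectable 52-week effect profile for the comparison year, with
  multipliers on weekly activity probability and on expected total weekly
  volume.

Every dataset is emitted together with a truth ledger holding the exact
per-athlete-week totals, which downstream recovery tests use as oracle.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activity_store import AGE_GROUPS, ActivityTable
from .cohort import AthleteProfile, Cohort
from .weekly import N_WEEKS, build_week_calendar

logger = logging.getLogger(__name__)

#: Country mix loosely shaped like the study cohort: US- and UK-heavy with
#: a long tail of smaller contributors.
DEFAULT_COUNTRY_PROBS = {
    "US": 0.38,
    "GB": 0.21,
    "DE": 0.05,
    "CA": 0.05,
    "FR": 0.04,
    "AU": 0.04,
    "IT": 0.03,
    "NL": 0.03,
    "JP": 0.03,
    "BR": 0.02,
    "ES": 0.02,
    "SE": 0.02,
    "CH": 0.02,
    "IE": 0.02,
    "MX": 0.01,
    "NO": 0.01,
    "DK": 0.01,
    "ZA": 0.01,
}

MAJORS = ("New York", "London", "Boston", "Tokyo", "Chicago", "Berlin")


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults reproduce the study's cohort structure.

    ``mean_weekly_distance`` is the target cohort mean over all
    athlete-weeks (zeros included), from which the per-run lognormal
    location is derived in closed form.
    """

    n_athletes: int = 1000
    p_male: float = 0.76
    age_probs: tuple[float, float, float] = (0.34, 0.59, 0.07)
    country_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COUNTRY_PROBS)
    )
    weekly_activity_prob: float = 0.75
    runs_per_active_week: float = 3.28
    mean_weekly_distance: float = 29.2
    distance_sigma: float = 0.45  # lognormal shape, within athlete
    athlete_effect_sigma: float = 0.35  # lognormal shape, between athletes
    pace_mean: float = 5.85  # min/km
    pace_sd: float = 0.5
    duration_noise_sd: float = 2.0  # minutes per run
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_athletes < 1:
            raise ValueError("n_athletes must be >= 1")
        if not 0 <= self.p_male <= 1:
            raise ValueError("p_male must be a probability")
        if abs(sum(self.age_probs) - 1) > 1e-9:
            raise ValueError("age_probs must sum to 1")
        if abs(sum(self.country_probs.values()) - 1) > 1e-9:
            raise ValueError("country_probs must sum to 1")
        if not 0 < self.weekly_activity_prob <= 1:
            raise ValueError("weekly_activity_prob must be in (0, 1]")
        if self.runs_per_active_week < 1:
            raise ValueError("runs_per_active_week must be >= 1")
        for name in (
            "mean_weekly_distance",
            "distance_sigma",
            "athlete_effect_sigma",
            "pace_mean",
            "pace_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def mean_distance_per_run(self) -> float:
        """Per-run mean distance implied by the weekly calibration targets."""
        return self.mean_weekly_distance / (
            self.weekly_activity_prob * self.runs_per_active_week
        )


@dataclass(frozen=True)
class EffectProfile:
    """52 weekly multipliers injected into the comparison year.

    ``activity`` scales the per-week running probability; ``volume`` scales
    the expected *total* weekly volume (activity included), so a volume
    multiplier of 0.65 at some week means the measured mean weekly distance
    is 35% below baseline at that week.  The baseline year is implicitly
    all-ones.
    """

    activity: np.ndarray
    volume: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "activity", np.asarray(self.activity, dtype=float))
        object.__setattr__(self, "volume", np.asarray(self.volume, dtype=float))
        if self.activity.shape != (N_WEEKS,) or self.volume.shape != (N_WEEKS,):
            raise ValueError(f"profile requires {N_WEEKS} weekly multipliers")
        if (self.activity < 0).any() or (self.volume < 0).any():
            raise ValueError("multipliers must be non-negative")

    @classmethod
    def identity(cls) -> "EffectProfile":
        return cls(np.ones(N_WEEKS), np.ones(N_WEEKS))


def default_pandemic_profile() -> EffectProfile:
    """Piecewise-linear profile shaped like the observed 2020 trajectory.

    Parity through week 9, a dip to -24% total volume around week 12 (third
    week of March), a rebound to +18% around week 16 (third week of April),
    a long decline through the third quarter to -35% volume and -16%
    activity at week 39 (last week of September), and a return to parity by
    week 46.
    """
    weeks = np.arange(1, N_WEEKS + 1)
    vol_anchors = ([1, 9, 12, 16, 39, 46, 52], [1.0, 1.0, 0.76, 1.18, 0.65, 1.0, 1.0])
    act_anchors = ([1, 9, 12, 16, 39, 46, 52], [1.0, 1.0, 0.88, 1.08, 0.84, 1.0, 1.0])
    volume = np.interp(weeks, *vol_anchors)
    activity = np.interp(weeks, *act_anchors)
    return EffectProfile(activity, volume)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw athlete demographics; deterministic given ``config.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n = config.n_athletes
    genders = np.where(rng.random(n) < config.p_male, "M", "F")
    ages = rng.choice(AGE_GROUPS, size=n, p=config.age_probs)
    countries = sorted(config.country_probs)
    probs = np.array([config.country_probs[c] for c in countries])
    country = rng.choice(countries, size=n, p=probs / probs.sum())
    n_majors = rng.choice([1, 2, 3], size=n, p=[0.8, 0.18, 0.02])
    profiles = {}
    for i in range(n):
        majors = tuple(rng.choice(MAJORS, size=n_majors[i], replace=False))
        profiles[i] = AthleteProfile(
            athlete_id=i,
            gender=str(genders[i]),
            age_group=str(ages[i]),
            country=str(country[i]),
            majors=majors,
        )
    return Cohort(profiles, reference_year=2019, comparison_year=2020)


def _athlete_latents(config: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-athlete lognormal distance effect and pace, shared across years."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    n = config.n_athletes
    tau = config.athlete_effect_sigma
    effect = np.exp(rng.normal(-0.5 * tau**2, tau, size=n))  # mean-one
    pace = np.clip(rng.normal(config.pace_mean, config.pace_sd, size=n), 3.0, None)
    return effect, pace


def generate_year_activities(
    cohort: Cohort,
    year: int,
    profile: EffectProfile,
    config: CohortConfig,
) -> tuple[ActivityTable, pd.DataFrame]:
    """Simulate one year of daily running records plus the truth ledger.

    Per athlete-week: a Bernoulli activity draw with probability
    ``weekly_activity_prob`` x activity multiplier; conditional on running,
    1 + Poisson draws of run days placed uniformly (without replacement)
    within the week span; per-run lognormal distances scaled so the
    expected total weekly volume carries the profile's volume multiplier;
    duration = distance x athlete pace + noise.

    The ledger has one row per athlete-week with the exact simulated
    ``distance``, ``duration`` and ``runs`` totals (pre final-week
    adjustment), the oracle for all recovery tests.
    """
    calendar = build_week_calendar(year)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, year]))
    n = len(cohort)
    ids = np.asarray(cohort.athlete_ids)
    effect, pace = _athlete_latents(config)

    p_week = config.weekly_activity_prob * profile.activity
    clipped = p_week > 1
    if clipped.any():
        logger.warning(
            "activity multiplier drives probability above 1 in %d week(s); clipped",
            int(clipped.sum()),
        )
        p_week = np.minimum(p_week, 1.0)
    # realised activity multiplier after clipping; per-run scale keeps the
    # profile's *total* volume multiplier exact in expectation
    act_real = p_week / config.weekly_activity_prob
    with np.errstate(divide="ignore", invalid="ignore"):
        run_scale = np.where(act_real > 0, profile.volume / act_real, 0.0)

    sigma = config.distance_sigma
    mu = np.log(config.mean_distance_per_run) - 0.5 * sigma**2

    rec_dates: list[np.ndarray] = []
    rec_athletes: list[np.ndarray] = []
    rec_dist: list[np.ndarray] = []
    rec_dur: list[np.ndarray] = []
    ledger_rows = []
    for week in range(1, N_WEEKS + 1):
        w = week - 1
        days = calendar.days_in_week(week)
        active = rng.random(n) < p_week[w]
        idx = np.flatnonzero(active)
        n_active = idx.size
        runs = np.zeros(n, dtype=int)
        dist_week = np.zeros(n)
        dur_week = np.zeros(n)
        if n_active and run_scale[w] > 0:
            # running accrues per day, so the long final week (8 or 9 days)
            # carries proportionally more expected runs; the downstream
            # 7/8 or 7/9 adjustment converts it back to a 7-day rate
            lam = config.runs_per_active_week * days / 7.0
            r = 1 + rng.poisson(lam - 1.0, size=n_active)
            r = np.minimum(r, days)
            total = int(r.sum())
            rep = np.repeat(np.arange(n_active), r)
            # distinct run days: per-athlete random permutation of the span,
            # take the first r[j] positions
            day_order = np.argsort(rng.random((n_active, days)), axis=1)
            intra = np.arange(total) - np.repeat(np.cumsum(r) - r, r)
            offsets = day_order[rep, intra]
            per_run_mu = mu + np.log(effect[idx] * run_scale[w])
            dists = np.exp(per_run_mu[rep] + sigma * rng.standard_normal(total))
            durs = dists * pace[idx][rep] + rng.normal(
                0, config.duration_noise_sd, size=total
            )
            durs = np.maximum(durs, 1.0)
            runs[idx] = r
            dist_week[idx] = np.bincount(rep, weights=dists, minlength=n_active)
            dur_week[idx] = np.bincount(rep, weights=durs, minlength=n_active)
            start = np.datetime64(calendar.starts[w], "D")
            rec_dates.append(start + offsets.astype("timedelta64[D]"))
            rec_athletes.append(ids[idx][rep])
            rec_dist.append(dists)
            rec_dur.append(durs)
        ledger_rows.append(
            pd.DataFrame(
                {
                    "athlete": ids,
                    "week": week,
                    "distance": dist_week,
                    "duration": dur_week,
                    "runs": runs.astype(float),
                }
            )
        )

    ledger = pd.concat(ledger_rows, ignore_index=True)
    profiles = cohort.profiles
    if rec_dates:
        frame = pd.DataFrame(
            {
                "datetime": pd.to_datetime(np.concatenate(rec_dates)),
                "athlete": np.concatenate(rec_athletes),
                "distance": np.concatenate(rec_dist),
                "duration": np.concatenate(rec_dur),
            }
        )
        frame["gender"] = frame["athlete"].map({a: p.gender for a, p in profiles.items()})
        frame["age_group"] = frame["athlete"].map(
            {a: p.age_group for a, p in profiles.items()}
        )
        frame["country"] = frame["athlete"].map(
            {a: p.country for a, p in profiles.items()}
        )
        frame["major"] = frame["athlete"].map(
            {a: ";".join(p.majors) for a, p in profiles.items()}
        )
        frame = frame.sort_values(["athlete", "datetime"], ignore_index=True)
    else:
        frame = pd.DataFrame(
            {
                "datetime": pd.Series([], dtype="datetime64[ns]"),
                "athlete": pd.Series([], dtype=np.int64),
                "distance": pd.Series([], dtype=float),
                "duration": pd.Series([], dtype=float),
                "gender": pd.Series([], dtype=str),
                "age_group": pd.Series([], dtype=str),
                "country": pd.Series([], dtype=str),
                "major": pd.Series([], dtype=str),
            }
        )
    return ActivityTable(frame, year=year), ledger


def generate_stringency(
    countries: list[str], year: int = 2020, seed: int = 0
) -> pd.DataFrame:
    """Step-shaped daily stringency table: low winter, March rise, plateau.

    Scores are near zero before early March, ramp up over two weeks, and
    hold a sustained high plateau with small country-specific offsets and
    day-to-day noise, always within [0, 100].
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    start = dt.date(year, 1, 1)
    n_days = (dt.date(year, 12, 31) - start).days + 1
    doy = np.arange(1, n_days + 1)
    ramp = np.interp(doy, [1, 68, 85, n_days], [3.0, 3.0, 72.0, 68.0])
    frames = []
    for country in sorted(set(countries)):
        offset = rng.uniform(-10, 14)
        noise = rng.normal(0, 1.5, size=n_days)
        scores = np.clip(ramp + np.where(doy >= 68, offset, 0.0) + noise, 0, 100)
        frames.append(
            pd.DataFrame(
                {
                    "country": country,
                    "date": pd.to_datetime(start) + pd.to_timedelta(doy - 1, "D"),
                    "score": scores,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
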