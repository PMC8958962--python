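"""End-to-end orchestration: simulate -> analyze -> report.

Each step is a plain function over the library modules; the CLI wraps them
thinly.  Every run writes a JSON manifest with the full configuration,
seed and output digests so that a run can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activity_store import ActivityTable, daily_totals, read_activities, write_activities
from .cohort import Cohort, select_within_subject_cohort, write_demographics
from .inference import (
    BootstrapConfig,
    bootstrap_mean_test,
    cohens_d,
    run_weekly_inference,
    sidak_alpha,
)
from .relative import (
    count_relative_difference,
    stratify,
    volume_relative_difference,
)
from .stringency import (
    load_stringency,
    weekly_stringency,
    weighted_stringency,
    write_stringency,
)
from .synthetic import (
    CohortConfig,
    EffectProfile,
    default_pandemic_profile,
    generate_cohort,
    generate_stringency,
    generate_year_activities,
)
from .weekly import (
    N_WEEKS,
    active_athletes_per_week,
    adjust_final_week,
    aggregate_weekly,
    build_week_calendar,
    weekly_pace,
)

logger = logging.getLogger(__name__)

SUMMARY_VARIABLES = ("athletes", "runs", "distance", "duration", "pace")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(out_dir: Path, config: dict, outputs: list[Path]) -> Path:
    manifest = {
        "runcompare_version": __version__,
        "config": config,
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def simulate(
    config: CohortConfig,
    out_dir: str | Path,
    profile: EffectProfile | None = None,
    fmt: str = "parquet",
) -> dict[str, Path]:
    """Generate a two-year synthetic dataset with truth ledgers and manifest.

    Writes daily activity files for both years under the dataset naming
    convention, a 2020 stringency CSV, per-year truth-ledger CSVs and a
    manifest echoing every generation parameter with the seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if profile is None:
        profile = default_pandemic_profile()

    cohort = generate_cohort(config)
    outputs: dict[str, Path] = {}
    for year, year_profile in (
        (cohort.reference_year, EffectProfile.identity()),
        (cohort.comparison_year, profile),
    ):
        table, ledger = generate_year_activities(cohort, year, year_profile, config)
        outputs[f"activities_{year}"] = write_activities(table, out_dir, "d", fmt)
        ledger_path = out_dir / f"ledger_{year}.csv"
        ledger.to_csv(ledger_path, index=False, float_format="%.10g")
        outputs[f"ledger_{year}"] = ledger_path

    countries = sorted({p.country for p in cohort.profiles.values()})
    stringency = generate_stringency(countries, cohort.comparison_year, config.seed)
    outputs["stringency"] = write_stringency(stringency, out_dir / "stringency.csv")

    config_dict = dataclasses.asdict(config)
    config_dict["profile_activity"] = profile.activity.tolist()
    config_dict["profile_volume"] = profile.volume.tolist()
    outputs["manifest"] = _write_manifest(
        out_dir, config_dict, [p for p in outputs.values()]
    )
    return outputs


def _year_matrices(table: ActivityTable, cohort: Cohort):
    calendar = build_week_calendar(table.year)
    matrices = aggregate_weekly(daily_totals(table), calendar, cohort)
    return calendar, {
        var: adjust_final_week(m, calendar) for var, m in matrices.items()
    }


def _summary_row(
    variable: str,
    base_vals: np.ndarray,
    comp_vals: np.ndarray,
    diffs: np.ndarray,
    config: BootstrapConfig,
) -> dict:
    """One Table-1-style row: yearly means, relative difference (the mean of
    the already-percent diff sample), Cohen's d and bootstrap p."""
    mean_base = float(np.nanmean(base_vals))
    mean_comp = float(np.nanmean(comp_vals))
    diffs = diffs[np.isfinite(diffs)]
    rel = float(diffs.mean())
    try:
        d = cohens_d(diffs)
    except ValueError:  # zero-variance differences (e.g. identical years)
        d = float("nan")
    p = bootstrap_mean_test(diffs, config)
    return {
        "variable": variable,
        "baseline_mean": mean_base,
        "comparison_mean": mean_comp,
        "difference_pct": rel,
        "cohens_d": d,
        "p_value": p,
    }


def analyze(
    baseline_path: str | Path,
    comparison_path: str | Path,
    out_dir: str | Path,
    stringency_path: str | Path | None = None,
    by: str | None = None,
    n_resamples: int = 2000,
    family_alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, Path]:
    """Run the full within-subject weekly comparison between two years.

    Writes ``weekly_inference.csv`` (52 rows of mean relative distance
    difference, bootstrap CI, p, Cohen's d, band, Šidák significance),
    ``summary.csv`` (five yearly rows: athletes, runs, distance, duration,
    pace), ``weekly_counts.csv``, optional per-stratum sub-analyses and the
    athlete-weighted weekly stringency series.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    baseline = read_activities(baseline_path)
    comparison = read_activities(comparison_path)
    cohort = select_within_subject_cohort(baseline, comparison)
    logger.info(
        "cohort: %d athletes, %d -> %d; B=%d, Šidák alpha=%.6f, seed=%d",
        len(cohort),
        baseline.year,
        comparison.year,
        n_resamples,
        sidak_alpha(family_alpha, N_WEEKS),
        seed,
    )

    config = BootstrapConfig(n_resamples=n_resamples, seed=seed)
    _, base_m = _year_matrices(baseline, cohort)
    _, comp_m = _year_matrices(comparison, cohort)

    outputs: dict[str, Path] = {}
    outputs.update(
        _analyze_cohort(base_m, comp_m, cohort, config, family_alpha, out_dir)
    )

    if by is not None:
        for stratum, ids in sorted(stratify(cohort, by).items()):
            if len(ids) < 2 or stratum == "unknown":
                continue
            sub_dir = out_dir / f"{by}={stratum}"
            sub_dir.mkdir(exist_ok=True)
            sub_cohort = Cohort(
                {a: cohort.profiles[a] for a in ids},
                cohort.reference_year,
                cohort.comparison_year,
            )
            sub_base = {v: _subset(m, ids) for v, m in base_m.items()}
            sub_comp = {v: _subset(m, ids) for v, m in comp_m.items()}
            sub_out = _analyze_cohort(
                sub_base, sub_comp, sub_cohort, config, family_alpha, sub_dir
            )
            outputs.update({f"{by}={stratum}/{k}": p for k, p in sub_out.items()})

    if stringency_path is not None:
        table = load_stringency(stringency_path)
        calendar = build_week_calendar(comparison.year)
        weekly_idx = weekly_stringency(table, calendar)
        counts: dict[str, int] = {}
        for p in cohort.profiles.values():
            counts[p.country] = counts.get(p.country, 0) + 1
        weighted = weighted_stringency(weekly_idx, counts)
        path = out_dir / "weighted_stringency.csv"
        pd.DataFrame({"week": range(1, N_WEEKS + 1), "weighted_score": weighted}).to_csv(
            path, index=False, float_format="%.6g"
        )
        outputs["weighted_stringency"] = path

    outputs["demographics"] = write_demographics(cohort, out_dir / "demographics.csv")
    config_dict = {
        "baseline": str(baseline_path),
        "comparison": str(comparison_path),
        "stringency": str(stringency_path) if stringency_path else None,
        "by": by,
        "n_resamples": n_resamples,
        "family_alpha": family_alpha,
        "seed": seed,
    }
    outputs["manifest"] = _write_manifest(
        out_dir, config_dict, [p for p in outputs.values()]
    )
    return outputs


def _subset(matrix, ids):
    from .weekly import WeeklyMatrix

    return WeeklyMatrix(matrix.variable, matrix.values.loc[ids], matrix.year)


def _analyze_cohort(
    base_m, comp_m, cohort, config: BootstrapConfig, family_alpha: float, out_dir: Path
) -> dict[str, Path]:
    outputs: dict[str, Path] = {}

    diff_distance = volume_relative_difference(comp_m["distance"], base_m["distance"])
    inference = run_weekly_inference(diff_distance, config, family_alpha)

    base_counts = active_athletes_per_week(base_m["distance"])
    comp_counts = active_athletes_per_week(comp_m["distance"])
    count_diff = count_relative_difference(comp_counts, base_counts)
    inference["count_diff_pct"] = count_diff.values

    path = out_dir / "weekly_inference.csv"
    inference.to_csv(path, index=False, float_format="%.8g")
    outputs["weekly_inference"] = path

    counts_path = out_dir / "weekly_counts.csv"
    pd.DataFrame(
        {
            "week": range(1, N_WEEKS + 1),
            "baseline_athletes": base_counts,
            "comparison_athletes": comp_counts,
        }
    ).to_csv(counts_path, index=False, float_format="%.8g")
    outputs["weekly_counts"] = counts_path

    rows = []
    rows.append(
        _summary_row("athletes", base_counts, comp_counts, count_diff.values, config)
    )
    for var in ("runs", "distance", "duration"):
        diff = volume_relative_difference(comp_m[var], base_m[var])
        rows.append(
            _summary_row(
                var,
                base_m[var].values.to_numpy().ravel(),
                comp_m[var].values.to_numpy().ravel(),
                diff.values.to_numpy().ravel(),
                config,
            )
        )
    pace_base = weekly_pace(base_m["duration"], base_m["distance"]).to_numpy().ravel()
    pace_comp = weekly_pace(comp_m["duration"], comp_m["distance"]).to_numpy().ravel()
    both = np.isfinite(pace_base) & np.isfinite(pace_comp)
    pace_diff = 100.0 * (pace_comp[both] - pace_base[both]) / np.nanmean(pace_base)
    rows.append(_summary_row("pace", pace_base, pace_comp, pace_diff, config))
    summary = pd.DataFrame(rows)
    path = out_dir / "summary.csv"
    summary.to_csv(path, index=False, float_format="%.8g")
    outputs["summary"] = path
    return outputs


def report(results_dir: str | Path, out_dir: str | Path) -> list[Path]:
    """Render the weekly overlay figure (and per-stratum panels if present).

    The overlay shows athlete counts, the mean relative volume difference
    with its bootstrap CI, and the weighted stringency trace when available.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results_dir = Path(results_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inference_path = results_dir / "weekly_inference.csv"
    if not inference_path.exists():
        raise FileNotFoundError(f"no weekly_inference.csv under {results_dir}")

    figures: list[Path] = []
    strata = sorted(p for p in results_dir.iterdir() if p.is_dir())
    panels = [results_dir] + [p for p in strata if (p / "weekly_inference.csv").exists()]

    fig, axes = plt.subplots(
        len(panels), 1, figsize=(9, 3.2 * len(panels)), squeeze=False, sharex=True
    )
    for ax, panel in zip(axes[:, 0], panels):
        inf = pd.read_csv(panel / "weekly_inference.csv")
        if inf.empty:
            raise ValueError(f"empty results in {panel}")
        ax.axhline(0, color="0.6", lw=0.8)
        ax.fill_between(inf["week"], inf["ci_low"], inf["ci_high"], alpha=0.3)
        ax.plot(inf["week"], inf["mean"], label="volume diff (%)")
        ax.plot(inf["week"], inf["count_diff_pct"], ls="--", label="athlete diff (%)")
        sig = inf[inf["significant"]]
        ax.plot(sig["week"], [inf["mean"].min()] * len(sig), "k.", ms=4)
        stringency_path = panel / "weighted_stringency.csv"
        if not stringency_path.exists():
            stringency_path = results_dir / "weighted_stringency.csv"
        if stringency_path.exists():
            s = pd.read_csv(stringency_path)
            twin = ax.twinx()
            twin.plot(s["week"], s["weighted_score"], color="tab:red", lw=0.9)
            twin.set_ylabel("stringency (0-100)", color="tab:red")
        title = "all athletes" if panel == results_dir else panel.name
        ax.set_title(title)
        ax.set_ylabel("relative difference (%)")
        ax.legend(loc="lower left", fontsize=8)
    axes[-1, 0].set_xlabel("week of year")
    fig.tight_layout()
    overlay = out_dir / "weekly_overlay.png"
    fig.savefig(overlay, dpi=120)
    plt.close(fig)
    figures.append(overlay)
    return figures


def run_synthetic_pipeline(
    config: CohortConfig,
    profile: EffectProfile | None = None,
    n_resamples: int = 2000,
    family_alpha: float = 0.05,
) -> dict:
    """In-memory simulate + analyze, returning the key intermediate objects.

    Convenience path used by tests and the worked examples; avoids file
    round-trips.  Returns cohort, per-year weekly matrices, the distance
    diff matrix, the weekly inference frame and weekly counts.
    """
    if profile is None:
        profile = default_pandemic_profile()
    cohort = generate_cohort(config)
    base_table, base_ledger = generate_year_activities(
        cohort, cohort.reference_year, EffectProfile.identity(), config
    )
    comp_table, comp_ledger = generate_year_activities(
        cohort, cohort.comparison_year, profile, config
    )
    _, base_m = _year_matrices(base_table, cohort)
    _, comp_m = _year_matrices(comp_table, cohort)
    diff = volume_relative_difference(comp_m["distance"], base_m["distance"])
    inference = run_weekly_inference(
        diff, BootstrapConfig(n_resamples=n_resamples, seed=config.seed), family_alpha
    )
    base_counts = active_athletes_per_week(base_m["distance"])
    comp_counts = active_athletes_per_week(comp_m["distance"])
    return {
        "cohort": cohort,
        "baseline_matrices": base_m,
        "comparison_matrices": comp_m,
        "baseline_ledger": base_ledger,
        "comparison_ledger": comp_ledger,
        "diff": diff,
        "inference": inference,
        "count_diff": count_relative_difference(comp_counts, base_counts),
    }
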