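"""Non-parametric resampling inference for weekly difference samples.

The weekly difference distributions are symmetric but far from normal
(excess zeros from inactive weeks, long tails from occasional very long
runs), so all interval estimation and testing is done by the bootstrap:

* percentile bootstrap confidence interval for the mean;
* two-sided bootstrap test of a zero population mean, where the achieved
  significance level is the fraction of resamples — drawn after translating
  the sample to mean zero — whose mean is at least as extreme as the
  observed one (Efron & Tibshirani's single-sample mean test);
* within-subject Cohen's d = mean / SD of the difference scores, mapped to
  the conventional bands very small (0.01), small (0.2), medium (0.5),
  large (0.8), very large (1.2), huge (2.0);
* Šidák familywise correction over the 52 weekly tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .relative import DiffMatrix
from .weekly import N_WEEKS

logger = logging.getLogger(__name__)

#: lower |d| threshold -> band label, descending
EFFECT_BANDS = (
    (2.0, "huge"),
    (1.2, "very large"),
    (0.8, "large"),
    (0.5, "medium"),
    (0.2, "small"),
    (0.01, "very small"),
)

_CHUNK_RESAMPLES = 500  # caps resample-index memory at ~chunk*n*8 bytes


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling settings.

    ``n_resamples`` defaults to the full 100,000; reduce for interactive
    work (the point estimate is unaffected, intervals stabilise well below
    the default).  ``p_smoothing`` selects the raw resample fraction or the
    (count+1)/(B+1) estimator that avoids literal zero p-values.
    """

    n_resamples: int = 100_000
    ci_level: float = 0.95
    seed: int = 0
    p_smoothing: str = "add_one"

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if self.p_smoothing not in ("raw_fraction", "add_one"):
            raise ValueError("p_smoothing must be 'raw_fraction' or 'add_one'")


def _bootstrap_means(x: np.ndarray, n_resamples: int, rng: np.random.Generator) -> np.ndarray:
    """Means of ``n_resamples`` with-replacement resamples of ``x``."""
    n = x.size
    out = np.empty(n_resamples)
    # cap the index block at ~2e7 entries regardless of sample size
    chunk = max(1, min(_CHUNK_RESAMPLES, int(2e7) // n))
    for start in range(0, n_resamples, chunk):
        stop = min(start + chunk, n_resamples)
        idx = rng.integers(0, n, size=(stop - start, n))
        out[start:stop] = x[idx].mean(axis=1)
    return out


def percentile_bootstrap_ci(
    x: np.ndarray, config: BootstrapConfig
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean.

    The interval is the pair of empirical quantiles (alpha/2, 1 - alpha/2)
    of the bootstrap distribution of the mean, with linear interpolation
    between order statistics.  Deterministic given ``config.seed``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("confidence interval requires a sample of size >= 2")
    rng = np.random.default_rng(config.seed)
    means = _bootstrap_means(x, config.n_resamples, rng)
    alpha = 1.0 - config.ci_level
    low, high = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return float(low), float(high)


def bootstrap_mean_test(x: np.ndarray, config: BootstrapConfig) -> float:
    """Two-sided bootstrap test of H0: population mean is zero.

    The sample is translated to mean zero (the null), resampled B times,
    and the achieved significance level is the fraction of resample means
    at least as extreme (in absolute value) as the observed mean.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("bootstrap test requires a sample of size >= 2")
    observed = x.mean()
    centered = x - observed
    if np.ptp(x) == 0 and observed != 0:
        logger.warning("degenerate sample: zero variance with nonzero mean")
    rng = np.random.default_rng(config.seed)
    means = _bootstrap_means(centered, config.n_resamples, rng)
    count = int((np.abs(means) >= abs(observed)).sum())
    if config.p_smoothing == "add_one":
        return (count + 1) / (config.n_resamples + 1)
    return count / config.n_resamples


def cohens_d(x: np.ndarray) -> float:
    """Within-subject Cohen's d: mean of the differences over their SD (n-1)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("Cohen's d requires a sample of size >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("Cohen's d undefined for a zero-variance sample")
    return float(x.mean() / sd)


def effect_band(d: float) -> str:
    """Conventional label for |d|: the highest band threshold not exceeding it."""
    if not math.isfinite(d):
        raise ValueError("effect size must be finite")
    magnitude = abs(d)
    for threshold, label in EFFECT_BANDS:
        if magnitude >= threshold:
            return label
    return "negligible"


def sidak_alpha(family_alpha: float, m: int) -> float:
    """Per-test level 1 - (1 - alpha)^(1/m) controlling familywise error."""
    if not 0 < family_alpha < 1:
        raise ValueError("family_alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return 1.0 - (1.0 - family_alpha) ** (1.0 / m)


class DistributionDiagnostics(NamedTuple):
    skewness: float
    excess_kurtosis: float
    jarque_bera: float
    zero_fraction: float


def distribution_diagnostics(x: np.ndarray) -> DistributionDiagnostics:
    """Shape diagnostics for a weekly difference sample.

    Jarque-Bera is assembled as (n/6)(S^2 + K^2/4) from the sample skewness
    S and excess kurtosis K; the zero fraction quantifies the zero-inflation
    from weeks without any running.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("diagnostics require a sample of size >= 4")
    s = float(stats.skew(x))
    k = float(stats.kurtosis(x))  # Fisher: excess kurtosis
    jb = x.size / 6.0 * (s**2 + k**2 / 4.0)
    zero_fraction = float((x == 0).mean())
    return DistributionDiagnostics(s, k, jb, zero_fraction)


def run_weekly_inference(
    diff: DiffMatrix, config: BootstrapConfig, family_alpha: float = 0.05
) -> pd.DataFrame:
    """Mean, CI, bootstrap p, Cohen's d and band for each of the 52 weeks.

    Each week's resampling is seeded with ``config.seed + week`` so weeks
    are independently reproducible.  Significance is judged against the
    Šidák-adjusted level for 52 tests.  A degenerate week (zero variance)
    yields NaN statistics rather than aborting the batch.
    """
    alpha_adj = sidak_alpha(family_alpha, N_WEEKS)
    rows = []
    for week in range(1, N_WEEKS + 1):
        sample = diff.weekly_samples(week)
        week_config = replace(config, seed=config.seed + week)
        try:
            low, high = percentile_bootstrap_ci(sample, week_config)
            p = bootstrap_mean_test(sample, week_config)
            d = cohens_d(sample)
            band = effect_band(d)
            significant = bool(p < alpha_adj)
        except ValueError as exc:
            logger.warning("week %d inference failed: %s", week, exc)
            low = high = p = d = float("nan")
            band = "undefined"
            significant = False
        rows.append(
            {
                "week": week,
                "mean": float(sample.mean()),
                "ci_low": low,
                "ci_high": high,
                "p_value": p,
                "cohens_d": d,
                "band": band,
                "significant": significant,
            }
        )
    return pd.DataFrame(rows)
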