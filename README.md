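# runcompare

Within-subject comparison of long-distance running training between two
calendar years, built for activity datasets of the kind recorded by GPS
sports-tracking platforms: millions of per-bout records (date, athlete,
distance in km, duration in min, demographics) for a fixed cohort of
runners observed in both a baseline and a comparison year.

The question it answers is epidemiological: did the cohort's weekly
training change between the years, week by week, and by how much —
controlling for seasonality (same weeks compared across years) and for
between-athlete level differences (every athlete is compared against
their own baseline)?

## The statistics at the core

For each athlete *a* and week *w* (52 whole weeks per year; the final
week spans 8 days in a 365-day year and 9 in a leap year and is rescaled
by 7/8 or 7/9 to a 7-day rate), the weekly volume difference is
normalized by a single baseline scalar:

    Δ(a, w) = 100 · (x_cmp(a, w) − x_base(a, w)) / x̄_base   [%]

where x̄_base is the mean over all athlete-week cells of the baseline
year (zeros included — an athlete who does not run in a week contributes
an exact zero). The weekly athlete count is treated analogously against
the mean weekly baseline count.

The resulting per-week samples are symmetric but heavily non-normal
(zero-inflated, long-tailed), so inference is fully non-parametric:

* **Percentile bootstrap CI** — empirical (2.5%, 97.5%) quantiles of the
  resampled mean, B = 100,000 by default;
* **Two-sided bootstrap mean test** — the sample is translated to mean
  zero, resampled, and the achieved significance level is the fraction
  of resample means at least as extreme as the observed mean;
* **Within-subject Cohen's d** — mean difference / SD of the differences,
  banded at |d| = 0.01 / 0.2 / 0.5 / 0.8 / 1.2 / 2.0 (very small …
  huge);
* **Šidák correction** — the 52 weekly tests are judged at
  1 − 0.95^(1/52) ≈ 0.000986 ≈ 0.001.

A country×day government-response stringency index (0–100) can be
averaged over the analysis weeks and across countries, weighted by each
country's athlete count, for side-by-side interpretation.

Because real multi-million-record datasets are not needed for testing,
the package ships a first-class synthetic cohort generator: zero-inflated
lognormal weekly volumes with athlete-level random effects, configurable
demographics, and a 52-week *effect profile* of multipliers on weekly
activity probability and total weekly volume, emitted together with a
truth ledger of every simulated athlete-week total.

## Worked example

```python
from runcompare import CohortConfig, sidak_alpha
from runcompare.pipeline import run_synthetic_pipeline

res = run_synthetic_pipeline(CohortConfig(n_athletes=2000, seed=42),
                             n_resamples=2000)
inf = res["inference"]
print(f"Sidak-adjusted weekly level: {sidak_alpha(0.05, 52):.6f}")
print(inf[inf["week"].isin([12, 16, 39])].to_string(index=False))
print(f"significant weeks: {int(inf['significant'].sum())}/52")
print(f"week-39 athlete-count difference: {res['count_diff'].values[38]:.1f}%")
```

prints (abbreviated):

```
Sidak-adjusted weekly level: 0.000986
 week       mean     ci_low    ci_high  p_value  cohens_d       band  significant
   12 -21.360064 -26.372355 -16.308932   0.0005 -0.183515 very small         True
   16  15.793688  10.366058  21.499153   0.0005  0.126557 very small         True
   39 -36.220538 -41.009323 -31.219110   0.0005 -0.326050      small         True
significant weeks: 21/52
week-39 athlete-count difference: -15.6%
```

The default effect profile injects a −24% volume dip at week 12, an +18%
rebound at week 16 and a −35% trough (with −16% active athletes) at week
39; the estimates above recover those multipliers from the simulated
records, with each week's mean inside its bootstrap CI and flagged
against the Šidák level. With 2,000 resamples the smallest attainable
smoothed p-value is 1/2001 ≈ 0.0005.

The same pipeline is available from the shell:

```sh
runcompare simulate --seed 3 --n-athletes 400 --format csv --out demo
runcompare analyze --baseline demo/run_ww_2019_d.csv \
    --comparison demo/run_ww_2020_d.csv \
    --stringency demo/stringency.csv --out demo/results
runcompare report --results demo/results --out demo/figs
```

`analyze` writes `weekly_inference.csv` (52 rows), a five-variable
yearly summary (`athletes`, `runs`, `distance`, `duration`, `pace`),
weekly athlete counts, the weighted stringency series, and a manifest
that makes the run byte-for-byte reproducible; `--by gender|age_group|
country` adds per-stratum sub-analyses.

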