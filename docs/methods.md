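# Methods

## Design

The analysis is within-subject: the cohort is fixed to every athlete
with at least one running record in the baseline year. Athletes who stop
running in the comparison year remain in the cohort and contribute
all-zero weeks; athletes first appearing in the comparison year are
excluded, since they have no baseline to be compared against. This
controls between-athlete level differences out of the year contrast, at
the price that the cohort can only shrink — a drop in active athletes is
expected from attrition alone and is reported, not tested away.

## Weekly aggregation

Weeks are consecutive 7-day blocks anchored at January 1 — not ISO
weeks. This is the only definition under which a 365-day year leaves one
trailing day and a leap year two, which are absorbed into week 52 (8 or
9 days). Outcome variables per athlete-week: distance (km) and duration
(min) are sums over the span; runs is the count of days in the span with
positive distance (multiple same-day bouts are first summed into daily
totals, so bout-level granularity ends there). Week 52 is multiplied by
7/8 or 7/9, converting it to a 7-day rate so all 52 values are
commensurable. The factor is applied to all weekly outcome matrices;
weekly athlete counts are computed from the adjusted matrices (a
positive week stays positive under scaling, so counts need no separate
correction). Weekly pace = duration / distance is left undefined (NaN,
never zero) for zero-distance weeks and those weeks are excluded from
pace averages.

## Relative differences

The volume denominator is a single scalar — the mean over every
athlete-week cell of the baseline matrix, zeros included. A per-athlete
denominator would explode for low-volume athletes and would not
reproduce the aggregate arithmetic that links the yearly means to the
printed percentage differences; the scalar form makes the mean weekly
relative difference interpretable as "percent of a typical baseline
week". Athlete counts use the mean weekly baseline count analogously.

## Bootstrap inference

* CI: percentile bootstrap of the mean, quantiles by linear
  interpolation between order statistics (numpy default). B = 100,000
  by default; the pipeline uses B = 2,000 for routine runs because the
  point estimate is B-invariant and interval endpoints stabilise well
  below the default. Note the granularity constraint: at level
  α′ ≈ 0.000986 a test can only reject if B ≥ ~2,000 when the smoothed
  p-value floor is 1/(B+1).
* Test: the sample is translated to mean zero before resampling — the
  standard single-sample construction of a mean-zero null for the
  achieved-significance-level test. Two-sidedness is by comparing
  |resample mean| against |observed mean|.
* p-smoothing: default (count+1)/(B+1), which cannot return an exact
  zero; the raw resample fraction is available where the literal
  fraction is wanted (it is what the exhaustive-enumeration tests
  check).
* Cohen's d uses the n−1 standard deviation; d is scale-free so the
  choice only matters at tiny n, and n−1 is the convention elsewhere in
  the package's variance estimates.
* Per-week runs are seeded `seed + week`, so any single week can be
  re-run in isolation and reproduce the batch bit-for-bit. A
  zero-variance week yields NaN statistics and `significant=False`
  instead of aborting the other 51 tests.
* Diagnostics: sample skewness, excess kurtosis and the Jarque–Bera
  statistic (n/6)(S² + K²/4) — assembled from scipy's moment estimators
  and cross-checked against `scipy.stats.jarque_bera` in the tests —
  plus the exact-zero fraction, which quantifies the zero-inflation.

## Stringency weighting

Daily country scores (validated to [0, 100]) are averaged within each
analysis week, then combined across countries weighted by each country's
*yearly* athlete count — the cohort's country composition, not weekly
active counts, so the weights are constants of the cohort. Countries in
the cohort but absent from the index table are dropped with a warning
rather than imputed.

## Synthetic data generator

The generator is the test bed for the entire chain and defaults to the
cohort structure the analysis is designed for:

| parameter | default | meaning |
|---|---|---|
| `p_male` | 0.76 | male share |
| `age_probs` | 0.34 / 0.59 / 0.07 | 18–34 / 35–54 / 55+ shares |
| `weekly_activity_prob` | 0.75 | chance an athlete runs at all in a week |
| `runs_per_active_week` | 3.28 | mean active days given any running |
| `mean_weekly_distance` | 29.2 km | cohort mean over all athlete-weeks |
| `distance_sigma` | 0.45 | within-athlete lognormal shape |
| `athlete_effect_sigma` | 0.35 | between-athlete lognormal shape |
| `pace_mean`, `pace_sd` | 5.85, 0.5 min/km | athlete pace distribution |

With these defaults the implied cohort mean runs/week is
0.75 × 3.28 ≈ 2.46. Per-run distance is lognormal with a mean-one
athlete-level multiplicative random effect; the lognormal location is
derived in closed form from `mean_weekly_distance`, which is why that
calibration is exact in expectation (the cap of run days at the week
length shaves well under 1%). Duration is distance × athlete pace plus
small Gaussian noise. Run days accrue per day, so the 8/9-day final week
draws proportionally more expected runs (mean scaled by days/7); the
downstream 7/8–7/9 adjustment then restores parity — without this, a
no-effect comparison year would show a spurious final-week deficit.

The effect profile holds 52 multipliers on activity probability and 52
on expected **total** weekly volume. Defining the volume multiplier on
the total (rather than on volume conditional on running) makes the
injected number directly comparable to the measured mean relative
difference: a 0.65 volume multiplier at week 39 is recovered as ≈ −35%.
Internally the per-run scale is volume/activity, with the activity
probability clipped at 1 (warning) and the scale compensated for the
realised clip. The default profile is piecewise-linear through parity
(weeks 1–9), a −24% dip (week 12), a +18% rebound (week 16), a −35%
volume / −16% activity trough (week 39) and parity from week 46.

Every simulated year is accompanied by a truth ledger of exact
per-athlete-week totals; the weekly aggregation is tested for exact
equality against it.

What the generator does **not** emulate: week-to-week persistence within
athletes (weeks are independent draws; an optional autocorrelation knob
was considered and left out for lack of a calibration target),
day-of-week structure (run days are uniform in the week), training
periodization, injuries, weather, or drift in demographics. Passing
recovery tests therefore show that the estimator chain is unbiased and
calibrated under the assumed zero-inflated lognormal structure — not
that real-world confounders are handled.

## Problem sizes and numerical choices

Routine tests and examples use cohorts of 150–2,000 athletes; the
end-to-end recovery check uses 5,000 athletes and B = 2,000, where the
week-39 standard error of the mean relative difference is ≈ 1.3
percentage points, comfortably inside the 5-point recovery tolerance.
Monte-Carlo operating characteristics are measured with 2,000 null
datasets (type-I error) and 1,000 datasets (CI coverage). Quantile
ties are broken by linear interpolation; all randomness flows from
explicit integer seeds through `numpy.random.default_rng`, and repeated
runs from the same manifest are byte-identical (CSV floats are written
with fixed formats).

## Known limitations

* The scalar volume denominator means stratified relative differences
  are normalized within each stratum, so strata with very different
  baseline volumes are each on their own percentage scale.
* The bootstrap mean test is mildly anti-conservative at small n with
  heavy tails (empirically ≈ 0.05–0.065 at n = 60); the Šidák-corrected
  operating point is far from this regime's edge.
* Country inference from activity locations is a modal vote with a
  lexicographic tie-break; true travel patterns are out of scope.
* Calendar weeks anchored at January 1 do not align across years by
  weekday, only by day-of-year — the price of whole-week coverage of
  both years.
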