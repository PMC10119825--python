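# Methods

`ucflow` studies short-term forecasting of daily patient arrivals at urgent-care
clinics when the data-generating process shifts abruptly — the situation created
by pandemic lockdown mandates.  Because real clinic arrival data are
confidential, the package pairs a structured synthetic generator with the full
evaluation protocol: a heterogeneous bank of forecasters, a weekly
expanding-window backtest under feature-set ablations, forecast-comparison
statistics, and Shapley attribution of individual forecasts.

## The synthetic demand model

Daily arrivals for one clinic follow an intensity that is a product of
multiplicative factors,

```
lambda_d = baseline * growth(d) * yearly(d) * weekday(d) * holiday(d)
           * year_end(d) * alert(level_d) * rebound(d)
```

- **baseline** — mean arrivals per day at the series start (default 180 for the
  large clinic, 72 — about 40% — for the small one, so the volume-dependent
  predictability contrast between facilities is reproducible).
- **growth** — compound trend, `trend_annual_pct` % per 365.25 days (default 2).
- **yearly** — a two-harmonic cosine peaking at day-of-year 196 (mid-July:
  Southern-Hemisphere winter, when respiratory illness drives demand), with
  multiplicative half-range `yearly_amplitude` (default 0.18).
- **weekday** — seven factors, Monday..Sunday, with weekend maxima and a
  midweek minimum (default 0.95, 0.85, 0.82, 0.86, 0.97, 1.25, 1.30): urgent
  care absorbs demand when GPs are shut.
- **holiday** — uplift on public holidays (default 1.3).  The built-in NZ rule
  covers the nationwide holidays (fixed dates plus the Easter pair via the
  computus; regional anniversary days and mondayisation are omitted because
  the flag marks elevated-demand days, not payroll rules).  Explicit date
  lists are accepted anywhere a rule is.
- **year_end** — the GP-closure uplift over Dec 27–Jan 5 (default 1.15).
- **alert / rebound** — the concept-drift mechanism.  A schedule of alert-level
  episodes (1–4) multiplies demand by `alert_effect[level]` (defaults 1.0,
  0.85, 0.65, 0.5); for 28 days after each level-≥3 episode a 1.1× rebound
  models pent-up demand.  Neither suppression nor rebound size is an estimate
  of any real clinic's response; they are illustrative magnitudes chosen once,
  with the level-4 default at 0.5 so the drift is large enough to separate
  adaptive from non-adaptive forecasters.

Counts are negative-binomial with mean `lambda_d` and variance
`lambda_d * (1 + alpha * lambda_d)`; `alpha` (`noise_dispersion`, default 0.02)
gives a coefficient of variation around 16% at baseline volume, a realistic
overdispersion for arrival counts.  `alpha = 0` returns the exact intensity
path as floats — the mode the closed-form tests use; stochastic draws are
integers.

The proxy panel is generated alongside: pedestrian counts (suppressed on
weekends and sharply under high alert levels, lognormal noise), weekly flu
prevalence (winter-peaking, missing over the configured summer weeks, imputed
as 0 downstream since prevalence is low when unreported), a weekly combined
search-trends signal (winter-elevated, spiking during level-≥3 episodes,
rescaled to max 100), a smooth feels-like temperature curve, the alert level
itself, the public-holiday flag and the ISO week number (1–53).

What the generator does **not** emulate: calendar-specific school-holiday
structure beyond the seasonal cycle, clinic closures, day-of-week-by-season
interactions, reporting artifacts, or any fitted resemblance to a real
clinic's series.  Passing tests therefore demonstrate that the *protocol and
statistics* behave correctly and that proxy-aware models adapt to drift *of
the kind generated here*; they do not certify accuracy levels on real data.

## Features and leakage control

Predictors follow a fixed dictionary: lags of the target at 7, 14, 364, 728
and 1092 days (`lag7d`, `lag14d`, `lag1`, `lag2`, `lag3`), the ISO week
number, the public-holiday flag, and the five proxies.  Because the shortest
lag equals the 7-day horizon, every lag for a test window is observed at the
forecast origin, so each day is predicted directly from its own feature row
(no recursive feedback, no error compounding).

For test rows beyond the origin, observational proxies (pedestrians, flu,
trends, feels-like) are carried forward from their last observed value —
the information a deployed system would have — while the alert level and
calendar columns are taken as known (announced policy; deterministic
calendar).  Three ablations are supported: `all`, `autoregressive_only`,
`proxy_only`.  The calendar columns travel with all three by default;
`ar_includes_calendar=False` confines them to `all`/`proxy_only` since their
ablation assignment is genuinely ambiguous.

Training rows use the proxy values actually recorded on each date (all
historical at fit time); rows whose lag history precedes the series start are
dropped.  The default scenario therefore starts in 2011 so that every
training row from the canonical 2014 training start has complete lags.

## The forecaster bank

Fifteen methods behind one fit/predict contract, negative forecasts clipped
to zero:

| name | type |
|---|---|
| Benchmark | same day last year × 1.05 (the in-house rule) |
| Naive | same day last year (random-walk persistence) |
| Naive (Enhanced) | lag-weighted persistence, weights [5,4,3,2,1] / 15 on lags (7,14,364,728,1092) |
| ARIMA | univariate, order by minimum AIC over p≤3, d≤2, q≤3 |
| kNN, SVR (NU), Ridge, Kernel Ridge | standardised tabular regressors |
| Random Forest, Gradient Boosting, CatBoost | tree ensembles (the CatBoost slot runs on LightGBM's boosted trees) |
| Prophet | additive structural seasonal model (see below) |
| Voting | weighted mean of Prophet, CatBoost, Random Forest, ARIMA (uniform weights) |
| Stacking | ridge meta-learner over Prophet, CatBoost, Random Forest |
| Averaging | per-day trimmed mean of Prophet, CatBoost, Random Forest, Voting, Stacking |

Hyperparameters default to the conventional defaults of each family and are
all exposed in configuration; none were tuned.  The SVR variant is the
nu-parameterised RBF machine with library defaults.  ARIMA carries no
exogenous regressors or seasonal terms — it is the classical univariate
benchmark; the weekly cycle is carried by the lag features of the tabular
models.  If no ARIMA candidate converges the model falls back to persistence
with a logged warning.

The structural seasonal slot is an ordinary-least-squares additive model:
intercept, linear trend, three yearly Fourier harmonic pairs, day-of-week
effects and a public-holiday indicator.  It spans pure weekly signals exactly
and is shift-equivariant, which the tests exploit.

**Ensembles.**  Voting weights default to uniform (no published weights
exist).  The trimmed Averaging model removes exactly one maximal and one
minimal prediction per day, even under ties.  Stacking reserves the last 8
weeks of the training range: bases are fitted on the head, their genuinely
out-of-sample forecasts on the tail become the meta-features, a ridge
regressor (regularised, because the meta-training set is small) maps them to
observed arrivals, the bases are refitted on the full range and their
test-window forecasts pass through the meta-learner.  Univariate bases
forecast the whole tail as a multi-step horizon in that scheme.

## The backtest protocol

Weekly 7-day test windows; training expands from the data start until it
reaches a 5-year cap (1826 days) and rolls thereafter — the natural reading
of an "expanding window" with a maximum-history constraint.  With data from
2014-01-01, first test 2017-01-01 and end 2022-06-30 the plan contains
exactly 286 windows.  Every bank member is refitted from scratch each window
(no warm starts); the pass is repeated per feature-set ablation, with
univariate methods re-run in each pass so within-window ranks compare all
bank members.  Failures are logged and recorded as missing, never silently
dropped; a model failing in more than 5% of its cells aborts the run with a
per-model summary.  A master seed deterministically derives a sub-seed per
(feature set, window, model), so reports are byte-reproducible.

## Evaluation

MAPE (primary, in %), RMSE and MAE; per-window MAPE ranks (1 = best, average
under ties) averaged into mean ranks; yearly tables keyed by the calendar
year of each window's test start, with the "±" spread reported as the
standard deviation of per-window MAPE.  Theil's U is computed on the
chronological concatenation of a model's window forecasts; U < 1 beats
one-step persistence.  Zero observations are excluded from MAPE with a
logged count (configurable to raise instead).

The Diebold-Mariano test uses the squared-error loss differential by
default, a rectangular-kernel long-run variance truncated at horizon−1
lags, the Harvey small-sample rescaling and t(T−1) p-values.  A
zero-variance differential (identical forecasts) is an error, not a p-value.
Calibration note: under an iid equal-variance null at T=286, h=7 the
statistic's true size is ≈0.06 — the familiar slight oversize of the
truncated rectangular kernel (at h=1 the size is ≈0.047).  The calibration
checks therefore run 4000 null replicates so the Monte-Carlo standard error
(~0.004) is small against the acceptance band; replicate count is a
precision choice, not part of the hypothesis.

Drift deterioration is `100·(MAPE_b − MAPE_a)/MAPE_a` between two years;
ablation improvement is `100·(MAPE_a − MAPE_b)/MAPE_b` with the better
(full-feature) set in the denominator, matching the published arithmetic.
Display rounding is half-away-from-zero to match printed integer
percentages.

## Shapley attribution

The value function is interventional: `v(S)` is the mean model output over
background rows with the instance's values spliced in on coalition `S`.
The exact estimator enumerates all `2^p` coalitions (p ≤ 15) and is the
package's correctness oracle; the permutation-sampling estimator walks
random feature orderings, reports per-feature Monte-Carlo standard errors
and distributes the efficiency residual uniformly so
`base + Σφ = prediction` holds exactly.  Backgrounds default to 200 rows
sampled from the training matrix.

The Voting ensemble is attributed as a single function — the weighted mean
of its bases' outputs.  Univariate bases (ARIMA, the structural model, the
naive rules) consume no feature row, so they enter as per-date constants:
their share appears in the base value `E[f(x)]`, not in any feature's φ.
This is a deliberate and visible choice; a feature-level attribution of a
model that never sees features would be fiction.

Global importance ranks features by mean |φ| and carries the per-instance
(value, φ) pairs needed for beeswarm-style summaries; the dependence
extraction emits (x, φ_x, colour) triples plus the φ=0 threshold line.  The
package emits plot-ready data, not rendered figures.

## Scaled-down study sizes

The packaged drift study (`ucflow.drift_study`) uses the reduced bank
(Benchmark, Naive, Naive (Enhanced), Ridge, a 60-tree Random Forest, and
Voting over Ridge + Random Forest + Naive (Enhanced)) on a 2014–2020
scenario with a level-4 lockdown halving demand in 2020, backtested weekly
through 2019–2020 (104 windows × 3 ablations), repeated over three seeds.
The demo pipeline covers 26 windows of 2017 with the same bank.  These sizes
are the package's own choices for a study that remains interactive on one
CPU; the full 15-method bank over 286 windows runs with the same code and
configuration surface.

## Known limitations

- Synthetic realism is structural, not fitted; absolute MAPE levels are not
  comparable to any real clinic's.
- The ARIMA grid search refits up to 48 candidates per window, which
  dominates full-bank runtimes.
- Stacking refits its bases twice per window (head fit + full fit).
- Proxy carry-forward assumes a one-day reporting latency for all
  observational proxies; real feeds have heterogeneous latencies.
- The traffic-light alert mapping after Dec 2021 (Green→1, Orange/Red→2)
  compresses the upper levels; scenarios covering that period should encode
  restrictions accordingly.
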