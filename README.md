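# ucflow

Forecasting daily patient arrivals at urgent-care clinics, seven days ahead,
when the demand process is hit by pandemic-style concept drift — and asking
whether quasi-real-time proxy signals (pedestrian traffic, flu surveillance,
search trends, weather, the legal alert level) keep the forecasts usable when
purely autoregressive models break.

The package is aimed at forecasting practitioners and health-operations
researchers.  Real clinic arrival data are confidential, so `ucflow` ships a
structured synthetic generator together with the complete study machinery:

- **simulate** — daily arrival counts with winter (Jun–Aug) peaks, weekend
  maxima, holiday and year-end uplift, multi-year growth, and abrupt
  alert-level-driven suppression with post-lockdown rebound, plus a matching
  proxy-covariate panel;
- **forecast** — a bank of 15 methods behind one contract: hand-checkable
  benchmarks (the in-house +5% rule, naive persistence, lag-weighted
  persistence, auto-tuned ARIMA), tabular regressors on a fixed feature
  dictionary (lags of 7/14/364/728/1092 days, calendar, proxies), an additive
  structural seasonal model, and Voting / Stacking / trimmed-Averaging
  ensembles;
- **backtest** — weekly 7-day test windows, training expanding to a 5-year
  cap, every model refit per window, repeated for three feature-set
  ablations (`all`, `autoregressive_only`, `proxy_only`);
- **evaluate** — MAPE/RMSE/MAE, per-window mean ranks, yearly breakdowns,
  Theil's U against one-step persistence,

  ```
  U = sqrt( Σ_t ((ŷ_{t+1} − y_{t+1})/y_t)² / Σ_t ((y_{t+1} − y_t)/y_t)² ),
  ```

  Diebold–Mariano comparisons with Harvey-corrected, autocorrelation-robust
  variance, and the drift statistics: year-over-year MAPE deterioration
  `100·(MAPE_b − MAPE_a)/MAPE_a` and feature-ablation improvement;
- **explain** — interventional Shapley values (exact coalition enumeration as
  the oracle, a permutation sampler for scale) with global-importance and
  pairwise-dependence extractions; `E[f(x)] + Σφ = prediction` holds for
  every attribution.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import ucflow as uf

# a two-regime scenario: a level-4 lockdown halves demand in 2020
cfg = uf.ScenarioConfig(
    start_date="2014-01-01", end_date="2020-12-31", baseline_level=180.0,
    alert_schedule=[("2020-03-26", "2020-05-13", 4), ("2020-08-12", "2020-09-21", 3)],
    alert_effect={1: 1.0, 2: 0.85, 3: 0.65, 4: 0.5}, seed=0,
)
series, panel = uf.generate_scenario(cfg)

windows = uf.make_windows(series.start, "2019-01-01", series.end)   # 104 weekly windows
study = uf.Backtest(series, panel, bank=uf.reduced_bank(seed=0), windows=windows)
results = study.run(seed=0)

yearly = results.yearly_breakdown()
sub = yearly[yearly.model.isin(["Voting", "Benchmark"])]
print(sub[["feature_set", "period", "model", "MAPE", "rank"]].round(1))
```

prints (seed 0):

```
        feature_set  period     model  MAPE  rank
                all    2019    Voting  13.4   2.2
                all    2020    Voting  17.2   2.4
                all    2019 Benchmark  19.5   5.3
                all    2020 Benchmark  37.0   5.2
autoregressive_only    2019    Voting  13.3   2.4
autoregressive_only    2019 Benchmark  19.5   5.4
autoregressive_only    2020    Voting  23.6   2.8
autoregressive_only    2020 Benchmark  37.0   5.2
         proxy_only    2019    Voting  15.8   2.4
         proxy_only    2020    Voting  18.3   2.2
         proxy_only    2019 Benchmark  19.5   4.3
         proxy_only    2020 Benchmark  37.0   4.7
```

Reading the numbers: in the stable year (2019) the Voting ensemble sits near
13% MAPE under any feature set.  When the lockdown regime arrives (2020), the
in-house benchmark — last year's value plus 5% — collapses to 37% MAPE, the
autoregressive-only Voting model deteriorates by 78%
(`uf.drift_deterioration`), but with the proxy features included the
deterioration is held to 28%, and even the proxy-only model (18.3%) beats the
benchmark.  That is the drift-mitigation effect the study design is built to
measure.  Explaining a lockdown-week forecast shows why:

```python
res = uf.explain_date(series, panel, uf.reduced_bank(seed=0), "2020-04-15",
                      model_name="Voting", method="sampled", seed=0)
print(res.to_frame().sort_values("phi").head(3).round(1))
```

prints

```
        feature  value   phi  base_value  prediction  phi_se
9   covid_level    4.0 -55.6       171.6        87.6     0.2
1        lag14d   94.0  -8.7       171.6        87.6     0.1
10       trends   78.4  -7.2       171.6        87.6     0.2
```

— the alert level (value 4) is by far the strongest negative contribution,
pulling the forecast from the background expectation E[f(x)] = 171.6 down to
87.6 patients/day during the lockdown week.

The same pipeline is scriptable from the shell:

```bash
ucflow simulate --config run.yaml --out data/
ucflow backtest --config run.yaml --out report.csv
ucflow evaluate --report report.csv --out metrics.csv
ucflow explain  --config run.yaml --model Voting --date 2020-04-15 --features all --out attrib.csv
ucflow report   --config run.yaml --out results/
```

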