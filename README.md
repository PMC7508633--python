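# searchsurge

Counterfactual ARIMA exceedance detection for search-interest surveillance.

Population-level search behaviour is a real-time, freely observable signal
of public health: when a stressor hits a country, queries for symptoms of
distress rise above their usual rhythm. `searchsurge` operationalises this
idea for daily relative-search-volume series of the kind Google Trends
exports (a 0–100 index with 100 at peak popularity):

1. **Baseline model.** Fit a seasonal ARIMA (p,d,q)(P,D,Q)₇ to a baseline
   period of the series, with orders chosen automatically: KPSS tests set
   the differencing order *d*, a seasonal-strength heuristic sets *D*, and
   a stepwise hill-climb over AICc chooses the ARMA orders
   (Hyndman–Khandakar scheme). Residuals are screened with a Ljung–Box
   portmanteau test.
2. **Counterfactual forecast.** Project the baseline model over an
   evaluation window — the expected search volume had the baseline process
   simply continued — with per-horizon standard errors
   se(h) = √(σ² Σ_{j<h} ψ_j²) from the model's ψ-weights, or with
   residual-bootstrap sample paths.
3. **Exceedance days.** Flag every evaluation day whose observed value
   strictly exceeds the one-tailed 95% bound (expected + 1.645·se). The
   per-series statistic is the number of flagged days.
4. **Association.** Across countries, correlate exceedance-day counts with
   epidemic burden using tie-aware Spearman rank correlation (Pearson
   correlation of midranks; two-sided p from the t approximation on n−2
   degrees of freedom).

The package ships a 19-country panel of exceedance-day counts for the
keywords *insomnia*, *depression* and *suicide* (local-language terms)
together with COVID-19 deaths and confirmed cases, cumulative to
2020-03-20 and increases over 2020-03-20 → 2020-04-19, plus a synthetic
generator that emulates Trends-like series with known injected effects so
the whole pipeline can be validated without any download.

## Worked example

```python
import searchsurge as ss

# a synthetic series under the default study conditions, with a sustained
# rise injected into the 31-day evaluation window
cfg = ss.SyntheticConfig(seed=3, noise_sd=2.0, effect_shape="step",
                         effect_magnitude=30.0, effect_onset=0)
series, effect_days = ss.generate_trend_series(cfg)

result = ss.run_country(series)          # fit baseline, forecast, flag
print(result.metadata["order"])          # (1,0,0)(0,1,1)[7]
print(result.n_days, "of", len(result.flags), "days exceed the bound")
# 31 of 31 days exceed the bound

# the published 19-country correlation grid from the packaged panel
for r in ss.reproduce_table1_correlations():
    if r.x_label == "days_insomnia" and r.y_label == "deaths_increase":
        print(f"rho={r.rho:.2f}, p={r.p_two_sided:.3f}")
# rho=0.64, p=0.003
```

The selected order says the baseline was best described by weekly-differenced
data with a short autoregression and a seasonal MA term; every evaluation day of
this series exceeded its one-tailed 95% counterfactual bound, as expected for
a step much larger than the baseline noise. On the packaged panel, insomnia
exceedance days correlate strongly and significantly with the increase in
COVID-19 deaths (ρ = 0.64), while depression and suicide day counts do not
(ρ = −0.12 and −0.07).

A `searchsurge` command-line interface mirrors the library
(`simulate`, `detect`, `run`, `table1` subcommands); see
`searchsurge --help`.

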