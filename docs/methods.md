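# Methods

## The statistic

For one (country, keyword) series of daily relative search volume
y_1..y_T on the Trends 0–100 scale, split the time axis into a baseline
window (default 2019-12-20 → 2020-03-19, 91 days) and an evaluation window
(2020-03-20 → 2020-04-19, 31 days). A seasonal ARIMA (p,d,q)(P,D,Q)_m model
is fit **once** to the baseline and never refit inside the evaluation
window, so its forecast is a pure counterfactual: the search volume expected
had the baseline process continued. Day t of the evaluation window is an
*exceedance day* when

    y_t > ŷ_t + z · se_t ,        z = 1.645 (one-tailed 95%)

with se_t = sqrt(σ̂² Σ_{j<t} ψ_j²) accumulated through the ψ-weights of the
model's MA(∞) representation (seasonal polynomials and differencing
operators multiplied in). The per-series statistic is the count of
exceedance days, at most 31 under the default window. Across countries the
day counts are correlated with epidemic-burden columns by Spearman rank
correlation with midranks for ties and a two-sided t-approximation p-value —
the appropriate choice here because day counts are small integers with many
ties.

Deliberate consequences of this definition:

* **No multiple-testing correction across days.** The statistic counts
  marginal one-tailed exceedances, so under a correctly specified null its
  expectation is ≈ 0.05 × 31 = 1.55 days. It is a graded intensity measure,
  not a family-wise detection test.
* **Strict inequality.** A day exactly at the bound does not count, so the
  z → statistic map is right-continuous and ties are deterministic.
* **Parameter uncertainty is not propagated** into se_t, matching standard
  ARIMA prediction-interval practice; coverage is therefore slightly
  anti-conservative at long horizons, which the null-calibration test
  quantifies empirically.

## Automatic order selection

The selection scheme follows Hyndman–Khandakar:

* **D (seasonal differencing, m = 7):** D = 1 when the seasonal strength
  1 − Var(remainder)/Var(seasonal + remainder) of a classical
  moving-average decomposition exceeds 0.64, else 0. This threshold
  heuristic is deterministic and cheap; an OCSB test would add a second
  unit-root machinery for little gain at n ≈ 91.
* **d (ordinary differencing):** the smallest d ≤ 2 whose d-times
  differenced series passes the KPSS level-stationarity test at the 5%
  critical value 0.463 (Bartlett long-run variance, lag truncation
  ⌊3√n/13⌋), computed on the seasonally differenced series when D = 1.
  A series that becomes exactly constant after differencing is treated as
  stationary (d = 0) inside selection.
* **p, q, P, Q:** starting from the four standard seeds
  (2,d,2)(1,D,1), (0,d,0)(0,D,0), (1,d,0)(1,D,0), (0,d,1)(0,D,1) (plus the
  no-constant null model), hill-climb by varying one of p, q, P, Q by ±1
  (also p and q, or P and Q, jointly) or toggling the constant, accepting
  any move that lowers AICc until no neighbour improves. Bounds default to
  p,q ≤ 5, P,Q ≤ 2. A constant is admitted only when d + D ≤ 1 (it is not
  identifiable under double differencing); it enters the ARMA equation as
  an intercept, i.e. the process mean times (1 − Σφ) when d + D = 0 and a
  drift when d + D = 1.

Each candidate is fit by exact Gaussian maximum likelihood **of the
differenced series** (statsmodels' state-space filter is the inner
likelihood evaluator; the innovation variance is concentrated out of the
optimisation, which changes nothing at the optimum). The effective sample
size for AICc is n − d − D·m and k counts AR + MA + seasonal terms, the
constant if present, and σ². A fit is rejected — treated as AICc = +∞ in
the search — when the optimiser fails to converge within 500 iterations
(projected-gradient tolerance 1e-8) or when any AR/MA characteristic root,
seasonal included, has modulus ≤ 1.001. The root guard keeps forecast
variances finite and mirrors common auto-ARIMA practice.

Residuals of the selected model are screened with a Ljung–Box test at
h = min(10, n/5) lags (min(2m, n/5) for seasonal models) with
h − (p+q+P+Q) degrees of freedom. A rejection (p < 0.05) is surfaced as a
warning and recorded in the run metadata, never escalated to an error: the
day-count statistic remains defined either way, and on real series a mild
residual autocorrelation is common at this sample size.

## Forecast bands

Two uncertainty methods share the point forecast (the conditional mean,
computed on the differenced scale and integrated back explicitly):

* **gaussian** (default): upper_t = ŷ_t + 1.645·se_t. The constant 1.645
  (rather than the exact 1.6449 quantile) is the conventionally printed
  value; it is configurable. This is the method the exceedance rule is
  defined with.
* **bootstrap**: B ≥ 100 future sample paths built as
  ŷ + Σ_j ψ_j ε (the model's exact linear forecast-error recursion) with
  innovations drawn i.i.d. with replacement from the centred fitted
  residuals; the upper bound is the per-horizon empirical 95% quantile with
  type-7 (linear) interpolation, so results are bit-reproducible given a
  seed. For Gaussian residuals the bootstrap bound converges to the
  gaussian bound at the Monte-Carlo rate, which the suite asserts at
  B = 5000.

## Synthetic study conditions

The generator builds series as

    level + amplitude · sin(2πt/7) + AR(1) noise (+ injected effect)

with defaults: 91 baseline + 31 evaluation days, level 50, weekly
amplitude 8, AR(1) coefficient 0.5, innovation SD 3, rescaled so the series
maximum is 100 (the Trends convention). The AR(1) noise is burned in for
100 steps so the baseline starts in stationarity. These values were chosen
as a realistic caricature of search series: a pronounced weekly cycle
dominating a moderately autocorrelated noise floor. The weekly component is
a single sinusoid rather than day-of-week dummies — one parameter suffices
to exercise the seasonal machinery (with these defaults its seasonal
strength exceeds the 0.64 threshold, so selection must handle D = 1).
Injected effects are confined to the evaluation window: a step (sustained
shift to the window end), a ramp (linear growth to the target magnitude),
or a pulse of fixed width. Multi-country panels give country i a step
covering exactly k_i evaluation days as a contiguous block **ending at the
window end**, mimicking a sustained pandemic-era rise; the true k_i are
returned as a truth table.

What the generator does **not** emulate: Google's sampling noise, its
rescaling across stitched query windows, integer quantisation artefacts at
low volumes (rounding is available but off by default), non-sinusoidal
weekday profiles, and calendar effects (holidays). Passing the synthetic
benchmarks therefore shows the statistical machinery is correct and
calibrated under the stated process, not that real Trends series satisfy
that process.

## Validation benchmarks

The suite checks, among unit-level oracles (closed-form MLEs, a brute-force
multivariate-normal AR(1) likelihood, exhaustive-search AICc equivalence,
KPSS against an independent implementation, Spearman against scipy):

* **Null calibration:** over 200 no-effect series under the default
  conditions the mean exceedance-day count must lie in [0.9, 2.5] —
  nominal 1.55 with slack for estimation error in both directions.
* **Power:** a sustained step of 5 baseline-SDs must be flagged on ≥ 25 of
  31 days.
* **Ranking recovery:** on a 19-country panel with true effect-day counts
  0..18 (fixed permutation, step magnitude 25, noise SD 2), Spearman rho
  between recovered and true counts must reach 0.9.
* **Published-panel reproduction:** the four published correlation cells
  (0.64, 0.60, −0.12, −0.07 after half-up rounding to two decimals) from
  the packaged 19-country panel, with the insomnia–deaths p-value below
  0.005.

Problem sizes (200 null series, 19-country panels, B = 5000 bootstrap
paths) were sized to give stable Monte-Carlo estimates while keeping a full
run of the suite in the minutes range on a single core.

## Known limitations

* The per-country day counts published for the real keywords are inputs
  (a packaged panel), not outputs: reproducing them requires the original
  Trends extracts, which have no deposited accession.
* Whether the original day flags used the Gaussian or the bootstrap bound
  is ambiguous in the source description; both are implemented, gaussian is
  the default, and the method used is recorded in run metadata.
* The stepwise search returns a local AICc optimum; the suite pins it to
  the exhaustive optimum only on a white-noise testbed.
* `"<1"` tokens in Trends exports parse to 0.5 (the interval midpoint);
  this is a documented, configurable convention, not a claim about the
  suppressed values.
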