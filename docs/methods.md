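# Methods

## The forecasting problem

The target quantity is the start day of a tree pollen season: the first day
on which the cumulative sum of daily airborne pollen concentrations
(grains/m³/day), accumulated from a fixed calendar date, reaches a
taxon-specific threshold — 5 grains from January 1 for *Alnus* and
*Corylus*, 15 grains from March 1 for *Betula*. The threshold is attained
with `>=` on the cumulative sum, which is the natural reading for integer
counts and remains well defined for fractional concentrations. Starts are
typed early/moderate/late by fixed inclusive day-of-year ranges
(*Alnus* 12–36 / 37–60 / 61–84; *Corylus* 11–36 / 37–61 / 62–85; *Betula*
87–95 / 96–104 / 105–113); an auxiliary constructor can derive three equal
periods from an observed [min, max] for new sites, but the fixed ranges are
the defaults.

The predictor of an approaching season is a *local minimum* of the trailing
5-day running mean of a daily temperature statistic — the daily maximum for
*Alnus*/*Corylus*, the four-observation daily mean
`(t_max + t_min + t_06 + t_18)/4` for *Betula*. The running mean at day *d*
averages days *d−4 … d* (so the value on Jan 1 uses Dec 28–Jan 1; the first
*Betula* value, on Mar 5, uses Mar 1–5); no look-ahead. A local minimum is
a day preceded by ≥ 2 strictly decreasing steps and followed by ≥ 2
strictly increasing steps of the running-mean series.

## The onset model

Each local minimum at day *d* with running-mean temperature *t₅* becomes a
binary case: label 1 iff the season started 1–10 days after the minimum
(offsets of 0 cannot occur — a minimum needs two rising days after it).
Minima less than 3 days before the start are excluded from **training**
(their outcome is foreseeable and would be leaked); **verification** of
held-out years applies no such exclusion. The model is a two-predictor
logistic regression

P(onset within 10 days) = logistic(β₀ + β_d·d + β_t·t₅),

fitted by unpenalised maximum likelihood (Newton–Raphson with step
halving; convergence when the largest score component falls below 1e−8 or
the largest parameter step below 1e−10; at most 100 iterations). Perfect
separation is detected (all cases correctly classified with diverging
linear predictor) and raised as an explicit error rather than returned as a
pseudo-fit. Diagnostics follow standard ML practice: standard errors from
the inverse observed information; both *t* statistics (residual df n−3) and
per-parameter Wald χ² (1 df) are reported, as both conventions are common
in the applied literature; coefficient 95 % CIs are normal-approximation
β ± 1.96·SE with odds-ratio CIs by exponentiation; the goodness-of-fit test
is the likelihood-ratio χ² against the intercept-only model with 2 df. The
log-likelihood uses the log-sum-exp form, stable for |η| into the hundreds
(relevant for the *Betula* intercept of −25.4).

Decision rule: forecast YES when the probability exceeds 0.5 (strictly;
a probability of exactly 0.5 forecasts NO). In verification reports the
probability is printed at two decimals and the 0.5 rule is applied to the
printed value, keeping every report row consistent with its own probability
column. This matters because coefficient sets are typically published to
three decimals: at that precision the digits of the probability beyond the
second are not meaningful, and thresholding the full-precision value can
flip a borderline cell (e.g. a case whose reconstructed probability is
0.5012 where the originally fitted model gave ≤ 0.5). Internal training
diagnostics (the classification table) threshold the exact probability.

Closed-form interpretation helpers: `odds_multiplier(c, predictor, delta)`
returns e^{β·Δ}, the multiplicative change in onset odds over Δ days or
Δ °C; `day_at_probability(c, t5, p)` solves β₀ + β_d·d + β_t·t₅ = logit(p)
for the day at which a probability level is reached at fixed temperature.

The bundled reference coefficients (per taxon: β₀, β_d, β_t = −3.588,
0.066, 0.185 for *Alnus*; −4.155, 0.074, 0.215 for *Corylus*; −25.413,
0.274, 0.352 for *Betula*) come from a fit to the Krakow 1991–2010
monitoring series. Where that source's running text and its parameter
table differ in the third decimal, the table values are used: they
reproduce the published held-out verification probabilities at two
decimals.

## Input handling

Weather CSVs (`date,t_min,t_max,t_06,t_18`, ISO dates, °C, `.` decimal)
are validated for date uniqueness and t_min ≤ t_max. Gaps of ≤ 2
consecutive days are linearly interpolated per field with a logged warning;
longer gaps abort feature extraction for that year — years with long
instrument outages should be excluded, not patched. Day-of-year numbering
is 1-based true calendar (Jan 1 = day 1, leap years respected).

## Synthetic studies

Real multi-decade series for these taxa are not publicly deposited, so the
package generates its own studies (`pollencast.simulate`):

- **Temperature**: daily mean = seasonal sinusoid with its minimum on
  Jan 15 (default January mean −2 °C, annual amplitude 10.5 °C — a
  Central-European profile) plus AR(1) Gaussian anomalies (lag-1
  autocorrelation 0.7, stationary SD 3 °C). The four per-day observations
  are the mean plus diurnal offsets (+4, −4, −2, +1.5 °C) with 0.5 °C
  jitter, re-ordered so the min/max invariants always hold. These defaults
  were chosen to make the 5-day running mean show a handful of pre-season
  local minima per winter, the regime in which the method operates; the
  generator claims no weather-model realism (no weather types, fronts,
  trends, or spatial structure).
- **Onset**: the year's local minima are walked in day order and each
  triggers the season with the model's own probability at (day, t₅); on
  the first success the start day is drawn uniformly 3–10 days later —
  inside the forecast window but outside the training-exclusion margin, so
  induced labels are clean. Years in which no minimum triggers are
  resimulated on a fresh deterministic substream; the truth file records
  the offset rule, the attempt index, per-year minima, the triggering
  minimum and the start day. Generating onsets through the model's own
  hazard (rather than an independent phenology model) makes parameter
  recovery by the downstream fit a well-posed end-to-end check of exactly
  the pipeline described above.
- **Pollen**: trace pre-start counts (an exponential ramp summing to a
  uniform 20–75 % of the threshold), a topping-up count on the start day,
  and a noisy Gaussian-bell season afterwards (peak 80 grains/m³, width
  8 days, lognormal noise). By construction the cumulative-sum rule
  recovers the prescribed start day exactly.

All generators are deterministic given (scenario seed, year index,
substream); rerunning a scenario reproduces byte-identical CSVs.

What passing on synthetic data does **not** show: that the temperature
process matches any station's climatology, that real onsets follow the
fitted hazard, or that the reported in-sample accuracies transfer to other
sites. A small bias source is accepted deliberately: a minimum that failed
its trigger draw can still fall within 10 days of a start triggered by a
later minimum (and vice versa), so induced labels are not perfectly i.i.d.
Bernoulli; measured CI coverage across replicated studies (tested at 200
replicates × 50 years) nevertheless stays in the nominal band.

## Test problem sizes

The suite exercises the oracle equivalences at 200–1000 random instances,
parameter recovery at 2000 cases, likelihood-ratio calibration at 500
replicates of n = 200, and CI coverage at 200 replicated 50-year studies —
sizes at which the Monte-Carlo bands quoted in the tests are stable.

## Known limitations

- Two predictors only (day, t₅); rainfall, chilling sums and photoperiod
  are out of scope, as are regularised or Bayesian fits.
- No season end/duration metrics and no percentage-based season
  definitions; the cumulative-sum start is the only season quantity.
- The 0.5 decision threshold is fixed, not tuned (no ROC analysis).
- Historical reference tables occasionally carry date ↔ day-of-year pairs
  inconsistent by one day; this package always computes true calendar
  day-of-year and does not emulate such discrepancies.
- Tie steps in the running-mean series terminate a monotone run (strict
  inequalities). The underlying convention is not documented in the source
  material; strictness matches the mathematical notion of a local minimum
  and keeps the detector deterministic.
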