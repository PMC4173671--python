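# Methods

## Overview

The package implements a five-stage analysis of predator–prey
phenological mismatch in an age-structured lake fish population:
(1) Gaussian phenology fits to seasonal count data, (2) a degree-day
egg-development model turning spawning phenology into hatching
phenology, (3) a signed match/mismatch index, (4) a centred,
dummy-interacted recruitment regression with leave-one-year-out (LOO)
backward selection, and (5) sliding-window coefficient-of-variation
(CV) summaries of abundance. A synthetic-data generator emulates the
whole system so every stage is testable without field data.

## Phenology fitting

Seasonal events (spawning, zooplankton development) are modelled as
Gaussian curves in time. Binned counts — weekly trap hauls labelled by
bin centre, bins half-open of width 7 days — are fitted by maximising
the multinomial log-likelihood with cell probabilities equal to Gaussian
CDF differences across each bin. Bin mass via CDF differences matters
because weekly bins are wide relative to typical spreads (σ ≈ 5–9
days); a midpoint-density approximation biases σ upward by roughly the
Sheppard correction (√(σ² + w²/12) − σ ≈ 0.3 day at σ = 7, w = 7),
which is visible in the retained least-squares cross-check and is why
the grouped likelihood is the default. Optimisation is Nelder–Mead on
(μ, log σ) started from count-weighted moments, parameter tolerance
1e-8. The grouped likelihood is exactly invariant to rescaling all
counts. Duration is defined as 4σ.

Preconditions: at least three non-empty bins and a positive total;
failures (empty season, insufficient bins, non-convergence, peak far
outside the observed season) are flagged per year with reason strings,
never interpolated or silently dropped.

Fitted peaks are real-valued days; observed days are 1-based within the
year. Binned series may carry half-integer centre labels.

## Degree-day hatching

Eggs spawned on day *d* accumulate max(0, T − 4.9 °C) from day *d* + 1;
hatching occurs on the first day the running sum reaches 97
degree-days. The day-after-spawning convention makes a constant 12 °C
yield exactly ⌈97/7.1⌉ = 14 days, the standard two-week development
anchor for perch at spawning temperatures. At constant temperature
T > 4.9 °C the closed form is ⌈97/(T − 4.9)⌉ days. The temperature
series is used on an integer-day grid; gaps up to 7 days are linearly
interpolated, longer gaps are an error, and never reaching the heat sum
raises an error rather than returning a sentinel.

Hatching phenology propagates three spawning quantiles: the peak (μ,
rounded to the nearest day before accumulation) and μ ± 2σ. The
hatching duration is the span between the hatch days of the ±2σ
spawners, matching the 4σ definition of spawning duration; under
constant temperature it equals the spawning duration (a pure shift),
and within-season warming compresses it because later-spawned eggs
develop faster. Within-clutch hatching spread is not modelled (empirically
most larvae of a clutch hatch within a day or two).

The mismatch index is PM = zooplankton peak − hatching peak, positive
when larvae hatch before the prey peak. This sign convention makes the
recruitment quadratic's optimum positive (≈ +9.2 days; see below).

## Recruitment regression

Records are per spawn year: spawners S, mean spawner size MS, age-3+
count CA and winter temperature WT in the recruits' first year of life,
disease flag P, mismatch PM, hatching duration LS, and recruits R
observed at age 2. The standard structure is

log R = β0 + β1^D·LS + β2·PM + β3^D·PM² + β4·S² + β5·CA + β6·WT + ε,

with D = low where CA is at or below the sample median, else high.
Design construction centres continuous predictors by their in-sample
mean *before* forming powers and interactions, so quadratics read as
curvature about the mean and the interaction columns per dummy level
partition the centred predictor (elementwise disjoint). The spawner
effect enters as a single centred quadratic S²: a positive β4 produces
recruitment rising with spawner numbers beyond a threshold. The
package's reference coefficient set (`TruthParams.windermere()`) is
β0 = 11.4828, β1^low = 0.8295, β1^high = 0.1209, β2 = 0.0607,
β3^low = −0.0033, β3^high = −0.0009, β4 = 2.2e-11, β5 = −2.9e-5,
β6 = −0.1637, ε s.d. 0.3 — in log-recruits per day, day², spawner²,
individual and °C respectively. Under low density dependence the
mismatch response peaks at −β2/(2β3^low) ≈ +9.2 days.

Fitting is OLS with classical standard errors; p-values use the t
distribution on n − k degrees of freedom, without multiple-testing
correction. Leverages (hat diagonal) are reported and sum to k.

### Cross-validation and selection

`loo_cv_rmse` implements the literal protocol: drop one year, refit,
predict it, repeat for all years, report the root mean squared
prediction error. By default centring means and the dummy median are
recomputed inside each training fold — the strict out-of-sample
contract (a held-out year influences neither the centring nor the
median it is predicted with). A fixed-design mode freezes the
full-sample design and refits only the coefficients, in which case the
result equals the closed-form PRESS statistic, residual/(1 − leverage),
to machine precision; this identity is the main correctness oracle.
The precondition is n ≥ k + 1 so that every training fold of n − 1
years supports k coefficients.

Backward selection starts from a full candidate model. At each step
every admissible single simplification is scored by LOO-CV RMSE; the
best is applied if it does not exceed the current model's score,
otherwise selection stops. Admissibility respects marginality: a dummy
interaction collapses to its plain term (one step), a quadratic may be
dropped, and a plain linear term may be dropped only when no quadratic
or interaction of the same predictor remains. Ties prefer removing the
higher-order term, then resolve lexicographically, making the trace
deterministic. AICc — n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1) with k
counting the intercept and the error variance — is computed along the
selection path as a cross-check; on strongly identified data the
AICc-best model on the path coincides with the CV-selected one.

A known property of this selection rule, confirmed here against an
independent brute-force implementation, is that LOO-CV model comparison
is asymptotically AIC-like: each truly inactive candidate term survives
with probability near P(χ²₁ > 2) ≈ 0.16 regardless of sample size or
noise level. Exact recovery of a sparse true model among several
inactive candidates therefore plateaus around 30–50%, not near
certainty; users wanting consistency should prefer the AICc path with a
complexity-penalised variant or screen by effect size. The package
implements the protocol as specified and documents this ceiling rather
than altering the rule.

Residual diagnostics on the selected model: lag-1 autocorrelation
against the ±1.96/√n bound, a Breusch–Pagan-type test of squared
residuals against fitted values for variance homogeneity, and the
Shapiro–Wilk statistic for normality, each reported pass/fail at
α = 0.05.

## Variability

The CV (sample s.d. over mean, n − 1 denominator) is computed in every
window of w consecutive years, w = 3…11, windows advancing by one year,
separately for the periods before and after a truncation year (the
split year belongs to the post period). The mean CV and its standard
error across window positions are reported per (period, w). The
standard error ignores the autocorrelation induced by overlapping
windows — a deliberate simplification, so the error bars understate
uncertainty; comparisons between periods at the same w are unaffected
in expectation. CV is exactly invariant to positive rescaling of the
series.

## Synthetic data

The generators mimic the statistical structure of the lake system, not
its mechanics:

- **Temperature**: annual mean + linear warming trend + cosine seasonal
  term + i.i.d. daily Gaussian noise (defaults: mean 10 °C, amplitude
  7 °C, peak day 210, trend 0.02 °C/yr, noise 0.6 °C).
- **Spawner catches**: N fish multinomially assigned to weekly bins
  with Gaussian(μ, σ) bin masses; counts conserve N exactly.
- **Zooplankton**: Gaussian seasonal curve sampled at a fixed interval
  with mean-one multiplicative lognormal noise, so counts stay
  non-negative and the noiseless curve is exact.
- **Recruitment**: the log-linear model above, applied to predictors
  drawn as PM ~ U(−5, 30) days, LS ~ N(14, 3²) days, S ~ logN(ln 30000,
  0.4²), CA ~ logN(ln 20000, 0.5²), WT ~ N(4, 1²) °C. These stand-in
  distributions span both historical mismatch regimes (three-to-four
  week offsets and near-synchrony) and keep the design well
  conditioned; they are not estimates of the real covariate
  distributions.
- **Abundance**: two-regime lognormal (per-period median and log-s.d.)
  around a truncation year, the qualitative signature of an age–size
  truncation: a level shift plus inflated variance.
- **Full scenario** (`simulate_dataset`): spawning and zooplankton
  peaks advance linearly at different rates (defaults −0.2 and −0.45
  days/yr), so the simulated mismatch drifts from large positive values
  toward synchrony over a 40-year run; recruitment is generated from
  the *true* simulated phenology, so downstream estimation error
  remains visible to the analysis.

What the generator does not emulate: age-structured population
dynamics feeding back into spawner numbers, observation error in the
yearly covariates, serial correlation in recruitment residuals, skewed
or multimodal phenology, and temperature-dependent egg mortality.
Passing tests therefore demonstrate correctness of the estimators and
protocol under the assumed statistical structure, not robustness to
violations of it on real field data.

## Problem sizes and seeds

The validation experiments use 100 replicates of 300 years for
coefficient recovery (mean estimates within 3 Monte-Carlo standard
errors of truth; the S² coefficient has MC s.e. ≈ 4.5e-12 at these
conditions, so its relative uncertainty is the largest of the nine),
50 seeds at n = 200 for selection behaviour, 100 random small designs
for the PRESS identity, and 20 seeds of an 80-year two-regime series
for the variability pattern. All randomness flows through explicit
integer seeds into numpy Generators; there is no global random state.

## Known limitations

- The dummy split at the median CA changes within CV folds (by design);
  with tied or near-median values a single year can flip the split.
- The grouped likelihood assumes independent multinomial sampling of
  fish into weeks; trap saturation or weather-driven effort variation
  would violate this.
- Hatching propagates three spawning quantiles by default; the
  Monte-Carlo per-spawner mode (`hatch_phenology_mc`) exists as a
  cross-check and captures non-monotone within-season temperature
  excursions more faithfully, at simulation cost.
- LOO-CV backward selection is not model-selection consistent (see
  above); it optimises predictive error, not support recovery.
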