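# phenomatch

Analysis toolkit for predator–prey **phenological match/mismatch** in
seasonally reproducing fish populations, built around the Windermere
perch (*Perca fluviatilis*) – zooplankton system: when the timing of
larval hatching drifts away from the spring peak of zooplankton prey,
how strongly does recruitment suffer — and how does the population's
age–size structure (via competition and cannibalism by older fish)
modulate that sensitivity?

It is a library first (with narrative scripts under `examples/`), plus a
thin `phenomatch` command-line pipeline for shell use. Intended users are
fish and plankton ecologists and quantitative fisheries scientists who
want the full chain — phenology estimation, degree-day egg development,
mismatch indices, recruitment regression with predictive model
selection, and population-variability summaries — as tested, reusable
pieces, together with a synthetic-data generator that emulates the whole
lake system for power analysis and method validation.

## The model

**Phenology.** Weekly spawner catches and zooplankton counts in year *y*
are fitted with a Gaussian curve in time (grouped multinomial likelihood
over Gaussian bin masses, with a least-squares cross-check). The fitted
mean is the event's peak day; the duration is 4σ (the span of ~95% of
activity).

**Egg development.** Eggs spawned on day *d* hatch once the cumulative
daily temperature excess over a threshold reaches a fixed heat sum:
Σ max(0, T(t) − 4.9 °C) ≥ 97 degree-days, accumulating from the day
after spawning. At a constant 12 °C this gives the classic two-week
development time (⌈97/7.1⌉ = 14 days). Propagating the spawning peak and
its ±2σ quantiles yields the hatching peak and hatching duration LS_y.

**Mismatch.** PM_y = (zooplankton peak day) − (hatching peak day);
positive when larvae hatch before the prey peak.

**Recruitment.** With recruits R counted at age 2, all continuous
predictors centred, and D a low/high dummy split at the median number of
age-3+ fish CA (the competitors/cannibals):

```
log R_{y+2} = β0 + β1^D · LS_y + β2 · PM_y + β3^D · PM_y²
              + β4 · S_y² + β5 · CA_{y+1} + β6 · WT_{y+1} + ε_y
```

Model structure is pruned by backward deletion scored by
leave-one-year-out cross-validated RMSE (centring means and the dummy
median recomputed inside every training fold), cross-checked with
small-sample AICc, and validated by residual diagnostics
(autocorrelation, variance homogeneity, normality).

**Variability.** Population variability is the sliding-window
coefficient of variation (sample s.d./mean, windows of 3–11 years) of
yearly abundance, compared between the periods before and after an
age–size truncation event.

## Worked example

Fitting the recruitment model to 60 synthetic years generated from the
package's reference coefficients (`examples/04_recruitment_model.py`):

```
term          estimate        truth
const               11.44        11.48
LS:D_low           0.8241       0.8295
LS:D_high          0.1478       0.1209
PM                0.06844       0.0607
PM^2:D_low      -0.003678      -0.0033
PM^2:D_high    -0.0008763      -0.0009
S^2             4.456e-11      2.2e-11
CA             -2.808e-05     -2.9e-05
WT                -0.1671      -0.1637

R^2 = 0.982   LOO-CV RMSE = 0.310
```

The strong low-density effects (hatching duration 0.83 per day, mismatch
curvature −0.0033 per day²) are recovered closely; their high-density
twins are small, exactly the interaction pattern in which relaxed
density dependence makes recruitment sensitive to phenology. The
quadratic mismatch response under low density peaks at
−β2/(2·β3^low) ≈ +9.2 days: recruitment is maximal when larvae hatch
about nine days *before* the zooplankton peak.

The other scripts in `examples/` each print one stage: simulating the
lake (`01`), phenology fitting (`02`, peak 135.02 and σ 7.01 from 100k
fish with truth 135/7), hatching and mismatch (`03`, 14 days to hatch at
12 °C, PM = +25 days), and the variability shift (`05`, post-truncation
CV roughly double the pre-truncation CV at every window length).

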