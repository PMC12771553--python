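# Methods

## Heatwave definition and indices

Thresholds are the pooled percentiles (default 0.95) of daily Tmax and Tmin
over all May–October days of a reference period (default 30 years), per
location, with linear interpolation between order statistics at position
h = (n − 1)p + 1 (the numpy/R type-7 convention). Pooling all season days —
rather than a day-of-year window — matches the single warm-season percentile
definition the indices come from. "Exceeds" is strict (`>`): with continuous
temperatures the choice has measure zero, and it must be fixed for
reproducibility.

A heatwave is a maximal run of at least `min_duration` (default 2)
consecutive season days with Tmax or Tmin above threshold. Runs never span a
missing day, a non-season month, or a year boundary; a day with missing Tmax
or Tmin never qualifies and propagates downstream as missing exposure (the
panel drops it and logs the count) — no imputation. Events are classified
daytime-accentuated iff the event's cumulative Tmax excess strictly exceeds
its cumulative Tmin excess; exact ties go to nighttime-accentuated
(deterministic; ties have measure zero on continuous data).

Daily HWIs are computed on *all* heatwave days regardless of the containing
event's classification, so a day inside a daytime-accentuated event can
carry a positive nighttime index; the classification feeds only the binary
event flags. `compute_daily_hwi(..., zero_off_type=True)` zeroes the
off-type index per event for users who prefer the stricter reading; the
default keeps both daily indices because the model treats them as separate
same-day intensities.

## Design and estimation

Strata are (location, year, calendar month, ISO weekday; Monday = 1), so
each stratum holds 4–5 mutually comparable days and slowly varying
confounders cancel by design. Zero-count days are materialized: the count
model requires the full within-stratum day grid, not only case days.

The conditional quasi-Poisson fit maximizes the profile likelihood obtained
by conditioning on stratum totals (the multinomial/conditional-logit form):
one Newton iteration costs O(rows × params), so thousands of strata are
cheap, and the estimates agree with an explicit stratum-dummy Poisson GLM to
numerical precision (the test suite enforces < 1e−6 agreement against
statsmodels, and the single-stratum closed form ln(5/3)/2 to 1e−8).
Convergence is declared at a relative log-likelihood change below 1e−10,
with step halving and a 100-iteration cap; non-convergence raises with the
gradient norm. Strata with zero total count or without within-stratum
exposure variation contribute nothing and are excluded; if none remain, the
model is reported unidentifiable rather than silently returning zeros.

Dispersion is Pearson X²/df over the informative strata, with
df = rows − strata − exposure parameters. Standard errors scale by √φ with
*no* floor at 1 by default (pure quasi-likelihood); a configurable floor
(`ModelSpec.dispersion_floor`) is available. Scaling never moves point
estimates. When df ≤ 0 (e.g. a two-day single stratum) the fit reports
φ = NaN and leaves SEs model-based; the standalone dispersion computation
raises instead.

Spline exposure-response uses a natural cubic basis (linear beyond boundary
knots) per HWI, boundary knots at 0 and the observed maximum and two
interior knots at the 10th/50th percentiles of the HWI distribution. Knots
are placed on heatwave-day (positive) values by default: pooling the ~95%
zeros would collapse both interior knots to 0. Every basis column vanishes
at HWI = 0, so the curve is anchored at log-RR = 0 without post-hoc
centering. Lag models are separate single-lag fits (exposure joined at
day − k, k = 0..6); outcome days whose lagged date precedes season coverage
are dropped. A distributed-lag variant is out of scope. The humidity
sensitivity enters as a same-day linear covariate.

Heterogeneity tests operate on the percent-change scale — d = E₁ − E₂,
SE_d = √(SE₁² + SE₂²), normal z — because stratified results are reported on
that scale and published intervals can be inverted to SEs by
(hi − lo)/(2 × 1.96). Bonferroni families default to the number of
comparisons in the table at hand and the family size m is recorded next to
every adjusted p, since the appropriate family is analysis-specific.

## Attribution

AF = 1 − e^{−β·HWI} per day, location and heatwave type, against the
implicit counterfactual HWI = 0; AN = AF × observed count, summed to annual
totals per type. Negative β yields negative (protective) AF, which is
propagated, not truncated. Uncertainty: (β₁, β₂) drawn jointly from a normal
with the fit's quasi-scaled covariance (default 1000 draws, seeded), annual
ANs recomputed per draw, percentile CIs reported; the CI of the total sums
both types within each draw, preserving their correlation.

## Synthetic data

The generator emulates the moments the analysis is sensitive to, not real
meteorology. Tmax = seasonal half-sine (26 °C at the season edges, peak
34 °C) + a linear warming trend (0.35 °C/decade, centred on the reference
midpoint, so the analysis period sits above its own climatology, as a
2006–2019 study period does above a 1981–2010 baseline) + an AR(1) anomaly
(ρ = 0.8, σ = 3.5 °C, seasons independent across years). A two-state Markov
chain (onset 0.05, persistence 0.85) switches humid episodes that compress
the diurnal range from 14 °C by γ = 6 °C; Tmin = Tmax − range + noise,
clipped to Tmin ≤ Tmax. These defaults were set once to land the simulated
descriptives in the neighbourhood of published warm-season climate summaries
for California ZCTAs (≈ 7–8 heatwave days of each type and ≈ 20 °C·days of
cumulative HWI per location-year). Locations are independent; no spatial
correlation is modelled.

Counts: stratum baselines log-normal around λ₀ = 2/day (SD τ = 0.3), day
mean exp(baseline + β₁·DHWI + β₂·NHWI + optional lag terms), Poisson or
negative-binomial (gamma–Poisson, variance μ + μ²/k). Default effects anchor
to published per-degree percent changes: β₁ = ln(1.0034), β₂ = ln(1.0123).
Subgroup attributes are assigned by multinomial thinning with configurable
proportions. Four random streams (climate, humidity, baselines, counts) are
spawned from one seed so perturbing one leaves the others bit-identical.
The truth sidecar records the exact per-year expected excess
Σ μ·(1 − e^{−β·HWI}) per type, the oracle for the attribution tests.

Scenario registry: `null` (β = 0; 15 locations × 2 seasons — sized to give
stable Wald-calibration Monte Carlo at modest cost), `paper_anchored`
(50 × 3, the calibration workhorse), `overdispersed` (k = 1),
`lagged` (effect only at lag 2), `nighttime_dominant` (γ = 9).

What passing the synthetic suite does *not* show: robustness to spatially
correlated exposure, to secular trends in baseline counts within a month, to
exposure measurement error from centroid assignment, or to outcome
misclassification — none of which the generator produces.

## Numerical and design notes

* A deterministic constant-climate configuration (zero seasonal amplitude,
  zero anomaly variance) produces no threshold exceedances and hence no
  events; with a nonzero seasonal cycle and zero noise the seasonal peak
  *does* exceed the pooled percentile of its own climatology every year —
  the flat configuration is the meaningful "no weather" null.
* The full-size scenarios run in well under a minute per replicate; the
  Monte Carlo suites (400-replicate type-I, 100-replicate recovery) are
  sized to keep total runtime at a few minutes while leaving binomial Monte
  Carlo error well inside the asserted bands.
* Known limitations: no distributed-lag model; no population-weighted
  centroid computation (the location→grid mapping is an input); subgroup
  effect modification is estimated by refitting filtered panels, not by
  interaction terms, mirroring stratified reporting.
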