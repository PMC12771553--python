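# hwcc — daytime/nighttime heatwaves and acute care utilization

`hwcc` is a Python package for estimating the short-term health impacts of
*daytime-accentuated* versus *nighttime-accentuated* heatwaves from daily
temperature series and daily health-event counts, and for converting those
estimates into an attributable burden. It is aimed at environmental
epidemiologists working with administrative health data (e.g. ZIP-code-level
acute care utilization counts) and gridded or station climate records.

## What it computes

**Heatwave indices.** For each location, the 95th percentiles of daily Tmax
and Tmin over May–October of a 30-year reference climatology define local
thresholds. A heatwave is ≥ 2 consecutive days on which Tmax *or* Tmin
strictly exceeds its threshold. An event is *daytime-accentuated* when the
cumulative excess of Tmax over the event exceeds the cumulative excess of
Tmin (typically dry heat), and *nighttime-accentuated* otherwise (typically
humid heat that fails to cool overnight). On heatwave days the daytime and
nighttime heatwave indices (HWIs) are the same-day excesses

&nbsp;&nbsp;&nbsp;&nbsp;DHWI = max(0, Tmax − thr_max),&nbsp;&nbsp;
NHWI = max(0, Tmin − thr_min),

and both are 0 on non-heatwave days.

**Effect estimation.** A time-stratified case-crossover design compares each
day with the other days of the same weekday × month × year × location
stratum, and the conditional quasi-Poisson model

&nbsp;&nbsp;&nbsp;&nbsp;log E(Y) = α + β₁·DHWI + β₂·NHWI + β₃·Stratum

is fitted with the stratum intercepts eliminated by conditioning on stratum
totals (numerically identical to a stratum-dummy Poisson fit, but scalable).
Pearson overdispersion φ scales the standard errors. Effects are reported as
the percent change per 1 °C of HWI, (e^β − 1) × 100, with binary-event,
natural-cubic-spline and single-lag (0–6 day) exposure variants.

**Heterogeneity and burden.** Two estimates E₁, E₂ with SEs are compared via
d = E₁ − E₂, SE_d = √(SE₁² + SE₂²) (Bonferroni-adjusted across subgroup
families), and the daily attributable fraction AF = 1 − e^{−β·HWI} converts
counts into annual attributable numbers per heatwave type, with parametric
Monte Carlo confidence intervals.

Because real statewide hospital data are confidential, the package ships a
synthetic-data generator (`hwcc.simulate`) that reproduces the relevant
structure — autocorrelated warm-season temperatures, humid episodes that
compress the diurnal range, and stratum-heterogeneous, optionally
overdispersed counts whose log-rate is linear in the daily HWIs — with known
ground truth for every downstream quantity.

## Worked example

```python
from hwcc import simulate, design, estimator, heterogeneity as het, attribution

study = simulate.simulate_dataset(simulate.make_scenario("paper_anchored"))
panel = design.assemble_panel(study.health, study.exposure, cause="mental")
fit = estimator.fit_conditional_poisson(panel)
day, night = fit.effect("dhwi", "daytime"), fit.effect("nhwi", "nighttime")
comp = het.compare_estimates(night, day)
ci = attribution.attribution_uncertainty(panel, fit, n_draws=1000, seed=1)
```

prints (via the obvious f-strings):

```
events: 558  panel rows: 27600  informative strata: 1637  phi: 0.97
daytime: +0.38% per degC (95% CI -1.57, +2.37; p=0.704)
nighttime: +1.51% per degC (95% CI -0.14, +3.19; p=0.073)
difference: +1.13 pp (95% CI -1.45, +3.71; p=0.389)
year 2011: AN total 46.7 (95% CI 2.2, 86.8), nighttime share 82.6%
```

The scenario's true effects are +0.34%/°C (daytime) and +1.23%/°C
(nighttime); one 50-location × 3-season replicate recovers them within its
(wide) confidence intervals, and averaging over replicates recovers them
closely — that calibration is what the test suite checks. `phi ≈ 1` says the
counts are consistent with Poisson variation within strata; the attribution
line reads: about 47 of that year's events are attributable to heatwaves,
~83% of them to nighttime-accentuated ones.

The same pipeline runs from the shell on delimited text files
(`location_id,date,tmax,tmin` and `location_id,date,cause,count,...`):

```bash
hwcc simulate --scenario paper_anchored --out data/
hwcc run-all --config config.yaml
```

with subcommands `thresholds`, `detect`, `exposure`, `panel`, `fit`,
`compare` and `attribute` for the individual stages.

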