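# heatcase

Case-crossover analysis of daily ambient temperature and hospital-visit
rates, with distributed lag non-linear models (DLNM) and conditional
logistic regression — plus a synthetic-data generator with a known
exposure–lag–response surface so the entire pipeline can be verified end to
end without access-restricted hospital microdata.

## Who this is for

Environmental epidemiologists studying short-term associations between a
pervasive exposure (here daily temperature, adjusted for relative humidity)
and acute health events such as alcohol- and substance-related hospital
visits. The package takes admission records, gridded daily weather, and
crosswalk/vulnerability tables, and produces cumulative percent-change
curves with 95% confidence intervals, overall and stratified by location,
sex, age group, and social-vulnerability tertile.

## The model

Each hospital visit (case day) is matched to the other days of the same
calendar month and year sharing its day of week (time-stratified
case-crossover), which controls season, trend, weekday patterns, and all
slowly varying individual characteristics by design. Within stratum *c* the
log-odds of the visit falling on a given day are modelled as

    logit Pr(Y_ci = 1) = α_c + Σ_{l=0..6} s(T, df)_lci + Σ_{l=0..6} s(RH, df)_lci

where the lag-specific natural-spline terms `s(·, df)` form a tensor-product
*cross-basis* over the exposure dimension (natural cubic spline, `df_var`
columns, knots at equally spaced percentiles) and the lag dimension
(intercept plus natural cubic spline in `log(lag+1)`, `df_lag` columns).
The stratum intercepts α_c cancel in the conditional likelihood, which is
maximized by damped Newton–Raphson with analytic derivatives. `(df_var,
df_lag)` are selected by minimum AIC over the grid {3,4} × {2,3,4,5}.

Results are reported as the cumulative percent change in visit rates,
`100·(exp(η) − 1)`, where η is the sum over lag days 0–6 of the
log-rate-ratio at a temperature versus the reference (the period-minimum
daily temperature by default), with delta-method 95% CIs. A secondary model
restricts to lags 0–1 with an unconstrained lag basis, and a sensitivity
analysis refits without the humidity terms and compares estimates
(Pearson R and least-squares slope).

## Worked example

Generate a synthetic study with a known linear surface (cumulative
log-rate-ratio 0.02 per °C above −10 °C), then run the pipeline:

```python
from heatcase import (SimulationTruth, LinearSurface, write_fixture_bundle,
                      AnalysisConfig, run_analysis, cohort, weather)
import heatcase.io as hio

truth = SimulationTruth(
    surface=LinearSurface(slope_per_degc=0.02, reference=-10.0),
    n_units=6, n_cells=4, period=("2001-01-01", "2002-12-31"), seed=1)
write_fixture_bundle(truth, "demo", target_cases=3000)

b = hio.load_bundle("demo")
kept, rep = cohort.apply_exclusions(b["admissions"])
print(f"exclusions: {rep.n_in} -> {rep.n_out} ({rep.percent_excluded}%)")
svi = cohort.assign_svi_tertiles(b["tract_svi"], b["area_weights"])
exposure = weather.build_exposure_table(b["grid"], b["population_weights"])
events = {"substance_related": cohort.extract_case_series(
    kept, "substance_related", b["cause_map"], svi, b["city_units"])}
cfg = AnalysisConfig(causes=("substance_related",), df_var=3, df_lag=4,
                     stratify=False, secondary_lag01=False)
res = run_analysis(events, exposure, cfg)
ct = res["substance_related"]["curves"]["overall"]
print(ct.percentile_contrasts[["percentile", "at_temperature",
                               "percent_change", "ci_low",
                               "ci_high"]].round(1))
```

Output:

```
exclusions: 2876 -> 2818 (2.0%)
 percentile  at_temperature  percent_change  ci_low  ci_high
         50            13.0             8.9   -57.2    177.2
         75            18.5            36.8   -45.7    244.5
         90            21.6            55.0   -40.5    303.7
         99            25.4            80.3   -37.5    419.8
```

2% of the simulated records were contaminated with a missing field and are
excluded. The cumulative percent change rises with temperature, as the
positive truth surface dictates (the true value at the 75th percentile,
18.5 °C versus the −9.2 °C reference, is `100·(exp(0.02·27.7) − 1) ≈ 74%`);
the intervals are wide because the contrast is taken against the observed
minimum temperature, where data are sparse — one replicate at a few
thousand cases is noisy, which is exactly what the replicated calibration
experiments in `heatcase.experiments` quantify.

The same pipeline is scriptable from a shell:

```bash
heatcase simulate --out demo --surface linear --cases 3000 --seed 1
heatcase build-exposure --grid demo/weather_grid.csv \
    --weights demo/population_weights.csv --out exposure.csv
heatcase report --bundle demo --out results/
```

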