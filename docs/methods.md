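# Methods

## Design

The package implements a time-stratified case-crossover analysis of daily
temperature and acute hospital visits. Every case event defines one matched
stratum: the admission day plus every other day of the same calendar month
and year sharing its day of week (3–4 control days). Because same-weekday
days are seven days apart, the 0–6-day lag windows of the case and control
days in a stratum are pairwise disjoint, so case and control exposure
periods never overlap. Matching on year-month and weekday removes
confounding by season, long-term trend, weekday patterns, and any
characteristic of the individual that is stable over a month.

Within stratum *c*, the probability that the visit fell on day *i* follows
a conditional-logistic model whose linear predictor is the sum of two
cross-bases (temperature and relative humidity) over lags 0–6. The stratum
intercepts cancel in the conditional likelihood

    ℓ(θ) = Σ_c [ x_case'θ − log Σ_r exp(x_r'θ) ],

which is concave and low-dimensional (≤ ~40 parameters). It is maximized by
damped Newton–Raphson with analytic gradient and Hessian and step-halving;
convergence is declared when the gradient max-norm falls below 1e-8
(default), and the coefficient covariance is the inverse observed
information. Strata whose design rows are constant carry no information and
are dropped with a logged count. Non-convergence and separation are flagged
on the result object, never raised.

## Cross-basis construction

The exposure dimension uses a natural cubic spline with `df_var` columns:
interior knots at equally spaced percentiles of the pooled case+control
lagged exposure distribution (`df_var = 3` → 33.3rd/66.7th percentiles) and
boundary knots at the observed min/max. The basis is built from cubic
B-splines with the two second-derivative-at-boundary constraints removed by
QR projection and the intercept column dropped; beyond the boundary knots
each column continues linearly with its boundary value and slope, so
contrasts at extreme temperatures are well defined. The lag dimension uses
an intercept column plus a natural cubic spline in `log(lag+1)` with
interior knots equally spaced on the log-lag scale (`df_lag = 4` → 2
interior knots), the conventional choice when effects concentrate at short
lags. The cross-basis entry for row *i* and column *(j,k)* is
`Σ_l v_j(x_il) L_k(l)`.

Centering is applied at prediction time: cumulative contrasts are formed
against a reference temperature via the gradient
`g_(j,k) = Σ_{l∈S} [v_j(at) − v_j(ref)] L_k(l)`, giving the log-rate-ratio
`g'θ` and delta-method variance `g'Σg`. This leaves the likelihood
invariant to the choice of reference. The reference defaults to the
observed minimum of the exposure series (the conventional choice for
reporting cumulative changes against the coldest observed day) and can be
overridden.

Degrees of freedom are selected by minimum AIC over the grid
`df_var ∈ {3,4} × df_lag ∈ {2,3,4,5}` (8 models), fitted per cause on the
full (unstratified) data; stratified analyses reuse the selected pair. AIC
ties closer than 1e-6 resolve to the smaller total df. The humidity terms
always share the temperature terms' structure.

The secondary 0–1-day analysis is a separate refit at `max_lag = 1` with an
unconstrained lag basis (one column per lag), because a two-point lag
spline would be artificial; the lag-{0,1} subset contrast from the 0–6
model is also emitted so both readings are available.

## Exposure construction

Relative humidity is computed per grid cell from temperature, specific
humidity, and surface pressure using the vapor pressure
`e = q·p/(0.622 + 0.378·q)` and the Magnus saturation vapor pressure
`e_s = 6.112·exp(17.67·T/(T + 243.5))` hPa, clipped to [0, 100]%. RH is
computed *before* spatial aggregation because it is non-linear in its
inputs; aggregating first would not commute. Cell values are then combined
into unit (ZIP-level) series with a precomputed population-weight crosswalk
whose per-unit weights must sum to 1 (tolerance 1e-9); tract-to-unit
intermediation is left to the crosswalk supplier since the composition of
linear maps is itself a linear map.

## Cohort rules

Causes are assigned from the first four diagnosis positions; an admission
can contribute to several causes. Code patterns of 3–4 digits (dots
removed) match as prefixes and 5-digit patterns exactly, mirroring
clinical-classification semantics at mixed granularity; the packaged cause
map is an illustrative example, not a certified crosswalk. Records with
missing or unparseable sex, age, date, or residential ZIP are excluded
("inaccurate" dates are operationalized as unparseable or outside the
configured study period); the exclusion report computes
`100·(n_in − n_out)/n_in` to one decimal. Age bins are left-closed:
[0,25), [25,45), [45,65), [65,∞). Unit-level vulnerability scores are
area-weighted tract values; units are ranked (ties broken by unit id for
determinism) and split into tertiles whose sizes differ by at most one,
with any remainder going to the lower tertiles.

## Synthetic data generator

The generator emulates the pipeline's restricted inputs at desk scale.
Daily cell temperature is `mean + amplitude·sin(2π(d − phase)/365.25) +
cell offset + AR(1) anomaly`; defaults (mean 10 °C, amplitude 12 °C, AR(1)
0.7, innovation sd 2.5 °C) give a mid-latitude continental annual cycle
with realistic day-to-day persistence. Humidity and pressure are generated
jointly by drawing a smooth target RH in (10, 95)% and inverting the
specific humidity, so recovered RH always lies in (5, 100). Case events
arise as daily Poisson counts per unit whose log-mean is a baseline plus
the summed surface contributions of lagged temperature — exactly the
structure the conditional-logistic DLNM assumes, so conditional on one case
per stratum the case-day distribution is the softmax of the true linear
predictor (verified by a goodness-of-fit test). Truth surfaces are named
families (null, linear, threshold) that vanish at their reference for all
lags (identifiability); a `target_cases` setting recalibrates the baseline
so the *expected* total equals it (Poisson totals vary by a few percent).
Records receive diagnosis codes drawn from the cause map, demographics from
configured margins (42% female, 75% inpatient, age-group probabilities
0.13/0.50/0.32/0.05), and an optional contamination fraction with one key
field blanked to exercise the exclusions. The default bundle is 4 years ×
30 units × 12 grid cells.

What the generator does **not** emulate: real geography or spatial
covariance of weather, realistic diagnosis-code frequency distributions,
within-person dependence of repeat visits, or reporting artifacts. Passing
tests therefore demonstrate the statistical machinery is correct under the
model's own assumptions, not that those assumptions hold in any particular
administrative dataset.

## Verification strategy and problem sizes

Every numerical component is checked against an independent oracle: the
spline basis against a truncated-power construction of the same space, the
cross-basis and contrasts against triple-loop summation (1e-12), the
conditional likelihood against brute-force softmax enumeration (1e-10), the
fitter against statsmodels' conditional logit and against no-intercept
logistic regression on pair differences (1e-6), and least-squares
sensitivity summaries against closed forms. Frequentist behavior is checked
by replicated simulation: 200 replicates at 1,000 expected cases under a
null surface (95% CI coverage of zero within [0.90, 0.99]) and 200
replicates at 2,000 expected cases under a linear surface with cumulative
log-RR 0.2 per +10 °C (mean estimate within 3 Monte-Carlo standard errors
of the truth, coverage within [0.90, 0.99]). The replicated experiments use
4 units × 2 years per replicate; the acceptance script defaults to 100/60
replicates for the same experiments, configurable on its command line.

## Numerical choices and edge cases

- Log-sum-exp in the likelihood is stabilized by subtracting the
  per-stratum row maximum.
- Newton steps solve against `−H + 1e-12·I` to tolerate an exactly singular
  information matrix at the start; step-halving guarantees ascent.
- Coefficient norms above 1e3 flag possible separation.
- `df = 1` exposure splines reduce exactly to an affine column; degenerate
  (duplicate) knots raise.
- Percent-change CIs use the standard-normal 97.5% quantile at full
  precision (1.9599639845…).
- Percentile temperatures default to the pooled case+control lagged
  exposure distribution; case-day-only is available via configuration, as
  the appropriate population is a matter of reporting convention.
- Events whose 6-day lag window precedes the exposure series' start are
  dropped with a logged count rather than imputed.
- All dates are civil dates in the proleptic Gregorian calendar; no
  time-zone arithmetic.

## Scope limits

Geospatial intersection (shapefiles) is out of scope — crosswalk weights
arrive precomputed. Only the time-stratified referent scheme is provided.
No penalized splines, robust variances, or multiplicity adjustments across
strata. Outputs are delimited-text tables; plotting is left to the user.
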