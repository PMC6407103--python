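# Methods

This note records the statistical models the package implements, the
assumptions behind them, the synthetic generator used to validate them, and
the numerical choices that matter for reproducing results.

## 1. Problem setting

A mobile platform repeatedly drives a fixed route past a large diesel
source (a classification railyard) while logging second-scale pollutant
concentrations and GPS position; an hourly wind record covers the campaign.
The analysis has three stages:

1. **Background estimation** — separate the slowly varying regional
   ("urban background") level from local plumes within each driving
   session.
2. **Spatial aggregation** — reduce the time series to medians on 50 m
   road segments, stratified by hourly wind category.
3. **Proximity regression** — model the log medians as a function of
   wind and proximity covariates, with and without spatially correlated
   errors.

## 2. Background estimation (`nearsource.background`)

The background is modelled as a low conditional quantile of the
concentration time series: local plumes only add mass above the regional
level, so the τ = 0.10 quantile of concentration as a smooth function of
time tracks the background while ignoring spikes.

- **Curve family.** Natural cubic spline in time. Basis columns follow the
  truncated-power construction with the natural (linear-beyond-boundary)
  constraint; boundary knots at the first/last observation time, interior
  knots at equally spaced quantiles of the observation times (robust to
  uneven sampling from stationary stops). Times are affinely rescaled to
  [0, 1] before basis evaluation for conditioning; this spans the same
  function space. `df = 1` degenerates to a straight line.
- **Degrees of freedom.** `df = max(1, round(session hours))`: the premise
  is that urban background varies on the hour scale, so each hour of
  driving buys one effective degree of freedom.
- **Fitting.** Exact minimisation of the check loss
  ρ_τ(z) = z·τ for z > 0, z·(τ − 1) otherwise, written as the standard
  linear program (residuals split into positive and negative parts,
  equality constraints y = Xβ + u − v) and solved with HiGHS on a sparse
  constraint matrix. The LP gives the *global* minimum, which is what the
  enumeration-oracle and spike-robustness tests rely on: multiplying
  observations above the curve by 10 cannot move an exact τ-quantile fit,
  whereas an approximate (IRLS-style) fit would drift.
- **Properties verified.** Objective equals a brute-force pair-enumeration
  oracle to 1e-8 on small instances; the fraction of observations strictly
  below the curve lies within τ ± (df + 1)/n (basic interpolation property
  of LP quantile regression); relative RMSE against the generating curve
  is ~5% on 4 h plume-laden sessions.
- **Sessions shorter than 30 min are rejected** — too little data to
  support even one hour-scale degree of freedom.

## 3. Wind classification and aggregation (`nearsource.spatial`)

Hourly wind is mapped to one of five categories. Speed ≤ 0.5 m/s is
**CALM** regardless of direction; otherwise direction d (degrees,
meteorological) falls in half-open sectors, lower bound owned by the
sector:

| category | sector |
|----------|--------|
| NNE | [337.5°, 360°) ∪ [0°, 112.5°) |
| SE  | [112.5°, 157.5°) |
| SSW | [157.5°, 292.5°) |
| NW  | [292.5°, 337.5°) |

A 0.1° sweep test verifies the partition is exhaustive and exclusive with
exactly these bounds (1350/450/1350/450 tenths-of-degree per sector).

The route is cut into 50 m segments; each GPS fix is snapped to the
nearest segment within 30 m (unassigned otherwise). Within each
segment × wind-category × channel cell the median concentration is kept,
with its observation count and the segment's distance to the yard
boundary (0 inside the yard). Cells with fewer than 5 observations or
segments farther than 1 km from the yard are excluded.

The **downwind** indicator marks segments east of the yard under SSW flow
and west of it under NNE flow; CALM, SE and NW hours are never downwind
(the yard's long axis runs north–south, so SE/NW flow is along-yard).

## 4. Proximity regression (`nearsource.regression`)

For log medians Y (natural log; non-positive medians are dropped and
counted):

Y = β₀ + β₁·calm + β₂·railyard + β₃·downwind + β₄·distance_km + ε

- **Independent errors.** OLS via statsmodels. Rank deficiency is detected
  with a pivoted QR and reported with the names of the offending columns.
- **Spatial errors.** Gaussian process error with exponential covariance:
  Cov(εᵢ, εⱼ) = σ²·exp(−φ·dᵢⱼ) for records in the *same* wind category
  (dᵢⱼ in meters between segment midpoints), plus τ² on the diagonal, and
  0 across categories — each wind stratum is an independent replicate of
  the spatial field. Estimated by maximum likelihood.
- **Profiling.** β (by GLS) and the total variance s² = σ² + τ² have
  closed-form profiles, leaving a 2-D bounded search over
  (log φ ∈ [log 1e-5, 0], w = τ²/s² ∈ [0, 1]) run with L-BFGS-B from five
  deterministic starts. The w = 1 boundary reproduces OLS *exactly*, which
  makes the σ² = 0 limit criterion structural rather than approximate.
  The covariance matrix is block-diagonal by wind category; identical
  per-category segment layouts share one Cholesky factorisation per
  likelihood evaluation. If a factorisation fails, escalating jitter
  (1e-10, 1e-8, 1e-6 on the correlation diagonal) is applied before
  giving up.
- **Standard errors** come from s²·(X'V⁻¹X)⁻¹ at the ML covariance
  parameters. Under σ² > 0 the spatial SEs are systematically larger than
  the OLS SEs (verified in simulation: ~2× on the distance coefficient at
  the default truth), reflecting the reduced effective sample size.
- **Interpretation.** Effects are reported as multiplicative factors
  exp(β) with 95% intervals exp(β ± 1.96·SE); e.g. β₄ = −0.693 is a
  halving of concentration per km. `interpret_effects` refuses
  non-converged fits.
- **Correlations** between channels use pairwise-complete Pearson
  correlation of log medians on the segment × wind-category grid, with a
  minimum-pairs threshold below which NaN is reported.

## 5. Synthetic generator (`nearsource.synthetic`)

Defaults are the study conditions, not tuned values:

- **Route/yard:** 500 × 2000 m yard, long axis north–south, centered at
  the origin; north–south roads at ±150, ±450, ±800 m from the yard edge
  plus a through-yard transect; 50 m grid → 280 segments. The spread of
  offsets to 800 m is what identifies the distance coefficient.
- **Sessions:** 19 sessions of 1.2–5.9 h at 1 s sampling, vehicle at a
  constant 5.4 m/s looping the concatenated route.
- **Signal model:** c(t) = background(t) · exp(x(t)'β) · noise(t) +
  plume(t). Background is a natural cubic spline through positive control
  points placed hourly (±15% around 10 ppb) — hour-scale variation by
  construction, matching the df-per-hour premise. Noise is multiplicative
  lognormal with sdlog = 0.05 (instrument-scale). Plumes are a Poisson
  process (12 h⁻¹) of pulses with lognormal amplitudes (median 10 ppb)
  and 30 s exponential decay, ≈30% duty cycle.
- **Wind:** hourly categorical draw (CALM 0.2, NNE 0.2, SSW 0.2, SE 0.25,
  NW 0.15), speed U(0.05, 0.5) m/s when calm and U(0.8, 8) otherwise,
  direction uniform within the sector.
- **Aggregated draws** (`simulate_aggregated`) skip the time-series layer
  and draw log medians directly from the regression model with GP errors
  (σ² = 0.25, τ² = 0.1, φ = 1/200 m⁻¹) — used for the regression-stage
  recovery and coverage studies. Multivariate normals are drawn through
  an eigendecomposition so exactly singular covariances (coincident
  segments with τ² = 0) give exactly identical draws.
- **Reproducibility:** all randomness flows from
  `np.random.SeedSequence(seed, spawn_key=...)`; a given config is
  bit-reproducible.

**Realism limits.** The generator is a calibration instrument, not an
emissions model: plume arrivals are independent of wind and position, the
vehicle never stops, GPS is noiseless, the background spline is exactly
in the fitted family (so background RMSE measures estimation error, not
model misfit), and the session-level generator draws no GP field (spatial
structure in the end-to-end study comes from plumes and sampling, not an
injected covariance). One identifiability limit shows up in the
end-to-end scenario: when local effects multiply concentrations *below*
the regional level on distant segments (distance decay with a zero
intercept), the low-quantile curve tracks that lower envelope, so the
estimated background fraction understates the generating one. A low
quantile cannot distinguish background from a persistent multiplicative
depression; the regression stage is unaffected because it uses raw
medians.

## 6. Validation summary

`tests/test_acceptance.py` holds one test per headline property; sizes
and seeds are fixed. `scripts/acceptance.py --seed N --out f.json` reruns
the same studies from scratch and writes the headline numbers. Typical
values (seed 1): background relative RMSE ≈ 0.05 (threshold 0.10), all
sign counts within the ±(df+1)/n band, OLS 95% CI coverage within
[0.92, 0.98] for every coefficient, spatial-model median β̂₄ within 10% of
−0.693 with SE ratio ≈ 2 over OLS, and an end-to-end distance factor
≈ 0.50 per km against a generating value of 0.5.
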