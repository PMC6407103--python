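# nearsource

Analysis pipeline for mobile air-quality monitoring around a large
near-ground emission source. A vehicle repeatedly drives a fixed route
past the source (the motivating case is a diesel classification railyard)
logging second-scale pollutant concentrations and GPS position; an hourly
wind record covers the campaign. `nearsource` turns those raw drives into
an answer to the question *how much does this source raise nearby
concentrations, and how fast does the effect decay with distance?*

The pipeline has three statistical stages:

1. **Background estimation.** Within each driving session the slowly
   varying regional level is estimated as the τ = 0.10 conditional
   quantile of concentration over time, fit as a natural cubic spline
   (one degree of freedom per hour of driving) by solving the check-loss
   minimisation as an exact linear program. Local plumes only add mass
   above the regional level, so a low quantile tracks the background and
   is provably immune to spikes.
2. **Spatial aggregation.** Measurements are snapped to 50 m road
   segments and reduced to medians per segment × hourly wind category
   (CALM ≤ 0.5 m/s, else NNE / SE / SSW / NW sectors). Sparse cells
   (< 5 obs) and segments beyond 1 km of the source are excluded.
3. **Proximity regression.** Log medians are modelled as
   `Y = β₀ + β₁·calm + β₂·railyard + β₃·downwind + β₄·distance_km + ε`
   under independent errors (OLS) and under a Gaussian-process error with
   exponential covariance `σ²·exp(−φd) + τ²·1{i=j}` within each wind
   category, fit by maximum likelihood with β and total variance
   profiled out. Coefficients are reported as multiplicative factors
   `exp(β)` with 95% intervals.

A fully parameterised synthetic generator (`nearsource.synthetic`)
reproduces the study conditions — route geometry, winds, plume-laden
time series, or aggregated tables with GP errors — with known truth, and
is what the validation suite measures the pipeline against.

## Worked example

```python
import nearsource as ns

cfg = ns.ScenarioConfig(seed=33)          # defaults = study conditions
route = ns.make_route(cfg)
agg, truth = ns.simulate_aggregated(cfg, route)   # 280 segments x 5 categories
design = ns.build_design(agg, "NO")

ols = ns.fit_independent(design)
sp = ns.fit_spatial(design)
print(ns.interpret_effects(sp))
```

Running `python examples/03_proximity_regression.py` (which is exactly
this) prints:

```
1400 rows (segment x wind category)
log-likelihood: OLS -1293.1, spatial -1012.8
fitted covariance: sill 0.264, nugget 0.106, range phi 0.0051 per m (truth: 0.25, 0.1, 0.0050)

multiplicative effects, spatial model (truth in brackets):
  intercept    x10.93 [10.00]  95% CI (9.10, 13.13)
  calm         x1.37 [1.35]  95% CI (1.08, 1.73)
  railyard     x1.67 [1.65]  95% CI (1.34, 2.07)
  downwind     x1.60 [1.49]  95% CI (1.26, 2.03)
  distance_km  x0.46 [0.50]  95% CI (0.35, 0.61)

spatial SE on distance_km: 0.146 vs OLS 0.066 -- accounting for spatial correlation widens the intervals
```

The other example scripts walk through the remaining capabilities, each
printing computed numbers with a one-line reading:

- `examples/01_background_estimation.py` — quantile-spline background on
  one plume-laden session (relative RMSE 0.048 against the generating
  curve; 10.0% of samples below the curve).
- `examples/02_wind_and_segments.py` — wind classification, 50 m
  segmentation, snapping and median aggregation, with geometric-mean
  concentrations by zone.
- `examples/04_full_pipeline.py` — the whole pipeline on a 6-session
  campaign generated with a distance factor of 0.5 per km; it recovers
  0.545 (spatial) / 0.555 (OLS).

## Command line

The same pipeline is runnable from the shell:

```sh
nearsource simulate --seed 5 --out data/          # write a synthetic campaign
nearsource run --config pipeline.yaml             # everything end to end
nearsource background|aggregate|fit|report ...    # individual stages
```

`run` writes `aggregated.csv`, `fits.json`, `coefficients.csv`,
`background_summary.csv` and `correlations.csv`, each stamped with a hash
of the producing configuration.

## Layout

- `src/nearsource/` — library: `background`, `spatial`, `regression`,
  `synthetic`, `pipeline`, `io`, `cli`, `studies`.
- `examples/` — narrative scripts, one per capability.
- `docs/methods.md` — models, assumptions, parameter choices and
  numerical details.
- `tests/` — unit/property tests plus the acceptance suite.
- `scripts/acceptance.py` — headline numbers as JSON.
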