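# Methods

`mobilegam` estimates near-road pollutant gradients from 1-minute mobile
measurements collected on walking routes around major roadways, while
adjusting for meteorology, traffic volume, spatial background and serial
correlation. This note documents the statistical model, the numerical
choices, the synthetic campaign generator, and the known limitations.

## The models

All models act on the natural log of the 1-min pollutant concentration,
`y_i = ln C_i`.

**Initial additive model (independent errors).**

    y_i = X_i β + f_1(d_1i) + f_2(d_2i) + f_s(s_i) + ε_i,   ε_i iid

`X_i` collects the linear covariates: per-minute traffic count on each
roadway (vehicles/min, from 15-min counter totals spread uniformly at 1/15
per minute), wind speed (m/s), temperature (°C), relative humidity (%), and
sampling-day indicator variables (first day is the reference). `f_1, f_2`
are penalized spline smooths of the distance from the observation to each
roadway; `f_s` is a penalized bivariate smooth of UTM location that absorbs
local sources other than the two roadways. For an elevated roadway the
distance is the *effective* (line-of-sight) distance `sqrt(h² + g²)`, with
`g` the horizontal nearest distance to the polyline and `h` the deck height
linearly interpolated at the nearest point; at-grade roads use `g`.

**AR-error model.** The 1-min residuals within one instrument's series in
one sampling shift are serially correlated. The AR model is two-stage:
(1) fit the additive model; (2) pool its residuals' autocovariances across
contiguous series (each series demeaned on its own, length-weighted),
run Levinson–Durbin for orders 0..p_max (default 5), and pick the order by
BIC (AIC available); (3) refit the same mean structure by penalized GLS
with the AR(p) coefficients fixed, whitening the response and design with
the exact innovations filter within each series. Correlation never crosses
series boundaries: the correlation unit is one backpack within one shift
(three simultaneous backpacks interleave in time, so grouping by shift
alone would corrupt the lag structure).

**Time-trend model.** Adds a sampling-shift main effect (replacing day
dummies, since shift nests day) and one centered smooth of elapsed time per
shift. All per-shift time smooths share a single smoothing parameter
(block-diagonal design and penalty); a shift too short for a spline
degrades to a centered linear term. Serial correlation is handled exactly
as in the AR model, with the structure estimated from the residuals of the
independent-errors fit of this same mean structure.

**Discretized line-source model.** Each roadway is cut into consecutive
10-m arclength segments (a short final remainder is kept). Each segment j
acts as an individual source with traffic weight `e_j` (the road's mean
per-minute count apportioned by segment length, then normalized to mean 1
— the kernel's scale is not identified separately from the weights). Both
roads share one distance kernel g: the design column for basis function
`B_k` is `Σ_j e_j B_k(d_ij)` with `d_ij = sqrt(h_j² + ‖s_i − m_j‖²)` to the
segment midpoint `m_j`. The model is `Xβ + pooled term + f_s(s)`. Two
curves are reported: the bare kernel `g(d)` (re-centered; shape only) and,
per road, the *net source profile* `Σ_j e_j g(d_ij)` evaluated at receptors
on a perpendicular transect from the road midpoint — the quantity
comparable to a direct distance smooth (the kernel itself is the
deconvolution of the net profile along the road and is necessarily
sharper).

## Smoothing machinery

* **Univariate smooths** are cubic B-splines with interior knots at
  quantiles of the observed covariate and an exact second-derivative
  roughness penalty (Simpson's rule per knot span is exact for the
  piecewise-linear second derivatives). A sum-to-zero constraint over the
  observed values is absorbed by a null-space reparameterization, removing
  exactly one coefficient.
* **Distance smooths** are built in `log(d + 10 m)`: knot placement and
  the roughness penalty then follow the multiplicative geometry of
  near-source dispersion, concentrating resolution where gradients live.
  The 10-m offset (about half a street width) keeps the coordinate finite
  at the road edge. The fitted term is still a smooth function of
  distance; with quantile knots in raw distance, penalized fits shrink a
  sharp near-road rise toward a straight line and can understate the
  within-100-m decrement by half or more.
* **The spatial smooth** is a low-rank thin-plate-style radial basis
  (`r² log r`) at a deterministic space-filling (farthest-point) subset of
  observed locations, with the thin-plate side conditions absorbed, an
  affine null space, the bending-energy penalty on the radial block, and a
  mean-centering constraint. In the regression fits the affine directions
  carry a second, separately selected shrinkage penalty (`affine="shrink"`),
  because distance to a straight road is itself (nearly) an affine function
  of location: a free affine surface is structurally confounded with the
  distance smooths' unpenalized linear directions, and the double penalty
  resolves the indeterminacy in favor of the distance terms.
* **Smoothing-parameter selection**: the independence-assuming additive
  model uses GCV (the classical criterion for such fits); the AR-error
  refits select by REML *on the whitened problem*, consistent with the
  fixed-AR-then-fit two-stage logic. Both criteria are evaluated in
  closed form per candidate λ (penalty blocks are disjoint or have
  orthogonal ranges, so the log pseudo-determinant separates), optimized
  by coordinate-wise Brent search on log10 λ in [−8, 10], relative
  tolerance 1e-4, at most 50 sweeps, deterministic start at λ = 1. Under
  serially correlated noise GCV under-smooths; this is deliberate for the
  additive model — its wide curve bands versus the AR model's narrow ones
  are a finding, not an artifact.
* **Inference.** Coefficient and curve intervals use the conditional
  covariance `(X'X + S_λ)⁻¹ σ̂²` on the whitened problem, given the
  selected smoothing parameters (no smoothing-parameter uncertainty —
  a documented limitation). Smooth-term p-values are Wald tests
  `b' V_f⁺ b` with `V_f` the frequentist covariance at fixed λ (the exact
  null covariance of the estimate, so penalty shrinkage cancels), referred
  to a chi-square on the covariance rank; they are approximate and ignore
  selection of λ and of the AR structure. Distance curves are re-centered
  at the minimum observed distance; the headline summary is the percent
  decrease within 100 m, `100·(1 − exp(η(100) − η(d_min)))`. Curve grids
  run from the minimum observed distance to 500 m in 5-m steps and are
  never extrapolated.
* **Degenerate inputs**: a distance covariate with < 25 distinct values
  falls back to `k = min(k, #distinct − 2)`; a single-level day or shift
  factor drops its dummies with a log note; calm minutes (wind speed 0)
  get the sector label `"calm"` and are excluded from wind-stratified
  refits; boundary wind bearings (exactly 45° or 90°) classify as upwind.

Defaults: `k = 10` per distance smooth, `k = 30` for the spatial smooth
(2 affine + 28 radial columns before centering), `k = 10` per-shift time
smooth, `p_max = 5`.

## The synthetic campaign generator

Field campaigns of this design are rarely deposited, so the generator is
first-class: it produces complete campaigns (observations, 15-min traffic,
1-min weather, road GeoJSON) with every truth component serialized
(`truth.json` for parameters, `truth_components.csv` row by row, so
`y = background + met + traffic + decay + spatial + trend + noise`
reconstructs exactly).

Design emulated: two line sources — an at-grade highway (N–S) and a bridge
(E–W) whose deck ramps 0 → 40 m — flanked by a 50-m street lattice with
frontage streets beside each source; three backpacks walk random-waypoint
routes along the streets at a variable 55–85 m/min pace, recorded each
minute (along-street positions are continuous, cross-street coordinates
sit on the lattice); 12 shifts of 165 min (two per day) by default.
Calibrations: traffic means 13.7 (bridge) and 36.7 (highway) vehicles/min
with realistic class and speed splits; log-normal wind speed with median
0.9 m/s and 95th percentile 3.6 m/s (~55% of minutes below 1 m/s) and
AR(1) persistence 0.85 in the log (1-min winds are strongly persistent —
without persistence, independence-assuming inference on the wind
coefficient would not be anticonservative and the AR model would have
nothing to fix); diurnal temperature around 26.3 °C and RH around 45.8%
anti-correlated with temperature; about 1% of rows are deliberate junk
(abnormally low readings, out-of-session timestamps) for the QC filter.

Preset truths (documented in each campaign's `truth.json`):

| preset | decay | within-100-m truth | noise |
|---|---|---|---|
| `ufp_default` | exponential, amplitude 0.288, range 60 m | 19.0% (5 → 100 m), upper half of the 15–20% target band, anticipating penalized-fit shrinkage of the sharp rise | AR(1), φ=0.6, marginal SD 0.35 |
| `pm25_default` | linear, 0.178 log units over 500 m | ≈3.5% | AR(3), φ=(0.35,0.20,0.15), marginal SD 0.19 |
| `null_decay` | none | 0 | as UFP |
| `sector_decay` | highway decay only under downwind minutes | as UFP downwind | as UFP |

Wind-speed coefficient truths are −0.046 (UFP) and −0.071 (PM2.5) per m/s
on the log scale; temperature, RH and traffic coefficients are likewise
fixed in the presets. The spatial background is a sum of three Gaussian
bumps (|amplitude| ≤ 0.15 log units, 100–140 m scales) away from the
roads. A mild shared within-shift trend (0.08 log units for UFP) is on by
default; the concurvity scenario used in testing raises it to 0.5 and
couples the wind-speed median to the same shape.

What the generator does **not** emulate: GPS position error, instrument
drift and inter-operator calibration offsets, congestion-dependent
emission factors, street-canyon dispersion, building wakes, and seasonal
variation. Passing tests therefore demonstrate that the estimators recover
the stated structure under the stated noise — not that field data meet
these assumptions.

## Problem sizes used in tests and the acceptance script

Model-recovery runs use 5-shift campaigns (≈2,475 usable rows, matching
the regression sample size of the campaign design emulated) over 20–50 seeds;
coefficient-recovery and coverage runs use 2-shift × 84-min campaigns
(≈500 rows) over 100–200 seeds. These sizes make every property estimable
while keeping a full run in minutes.

## Known limitations

* Percent-decrease estimates inherit penalized-regression shrinkage; with
  the log-distance basis the residual attenuation is a few percentage
  points at the campaign's signal-to-noise.
* A heavily smoothed fit reverts toward the `a + b·log(d+10)` null space,
  so a truly linear-in-distance decay is reproduced with a small log-shaped
  deviation (median ≈ 0.006 log units over the first 100 m on the PM2.5
  preset) — visible only when the true curve is exactly straight.
* CIs are conditional on the selected smoothing parameters and AR
  structure; p-values for smooths are approximate.
* The two-stage AR procedure treats the AR coefficients as known in the
  refit; their estimation error is not propagated.
* Models with a fitted spatial surface are not intended for out-of-sample
  exposure prediction; the surface is a statistical control, not a
  transportable exposure model.
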