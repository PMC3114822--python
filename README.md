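# mobilegam

Spatio-temporal additive regression for mobile-monitored traffic
pollutants.

Mobile monitoring — walking instrumented routes through a neighborhood and
logging 1-minute pollutant concentrations with GPS — can map near-road
exposure gradients that fixed regulatory monitors cannot see. But the data
are awkward: concentrations depend jointly on distance to several sources,
traffic volume, meteorology and time of day; successive minutes are
serially correlated along the route; and slow temporal drift masquerades
as spatial structure. `mobilegam` is for exposure scientists and
biostatisticians who need to untangle that: it quantifies the pollutant
decrement within the first ~100 m of major roadways, with honest
uncertainty, from exactly such campaign data.

## The model

For the log 1-min concentration `y_i`:

    y_i = X_i β + f_1(d_1i) + f_2(d_2i) + f_s(s_i) + ε_i

where `X_i` holds traffic counts per roadway (veh/min), wind speed,
temperature, RH and sampling-day dummies; `f_1`, `f_2` are penalized
spline smooths of distance to each roadway (line-of-sight `sqrt(h² + g²)`
for an elevated deck); and `f_s` is a low-rank thin-plate smooth of UTM
location. Four estimators build on this mean structure:

* **additive** — independent errors, GCV smoothing (the classical
  first-pass fit);
* **ar** — errors follow an empirically selected AR(p) process within each
  instrument-shift series; the fit is exact penalized GLS via the AR
  innovations filter, with REML smoothing on the whitened problem;
* **timetrend** — adds shift main effects and a smooth of within-shift
  time (shared smoothing parameter), same AR error treatment;
* **discretized** — replaces the distance smooths by 10-m road segments
  acting as individual traffic-weighted sources through a common distance
  kernel.

Every model reports adjusted distance-decay curves `η(d)` with pointwise
95% bands and the percent decrease within 100 m,
`100·(1 − exp(η(100) − η(d_min)))`.

Because real campaigns of this kind are generally not deposited, the
package ships a synthetic campaign generator (`mobilegam.synthetic_data`)
with fully documented ground truth — two roadways (one ramping to 40 m
elevation), scripted walking routes on a street grid, 15-min traffic
counters, low-wind meteorology, AR minute-scale noise — so every estimator
is testable end to end.

## Worked example

```python
import mobilegam

cfg = mobilegam.preset("ufp_default")   # ultrafine-particle campaign
cfg.n_shifts = 5                        # ~2,475 usable backpack-minutes
campaign = mobilegam.generate_campaign(cfg, seed=42)

frame, report = mobilegam.assemble_frame(
    campaign.observations, campaign.traffic, campaign.weather,
    campaign.sessions, campaign.roads, pollutant="ufp")
print(len(frame), dict(zip(report.reason, report.n_removed)))
# 2450 {'outside_session': 13, 'low_reading': 12}

res = mobilegam.fit_ar(frame)
print(res.ar.order, res.ar.phi.round(3), round(res.r2, 3))
# 1 [0.579] 0.31
for rid, curve in res.curves.items():
    print(rid, round(curve.pct_decrease_100m, 1))
# bqe 10.5
# wb 14.0
print(res.coefficient_ci("wind_speed"))
# (-0.0501..., -0.0634..., -0.0368...)
```

Reading this: the residuals carry first-order serial correlation
(φ ≈ 0.58, close to the generator's 0.6); after adjustment, ultrafine
concentrations drop by ~10–14% within 100 m of each roadway on this single
campaign (the truth is 19%; medians over many campaigns land in the
15–20% range, single campaigns scatter); each m/s of wind speed dilutes
concentrations by about 5% (truth −0.046 per m/s, covered by the CI).

The same workflow from the shell:

```bash
mobilegam simulate --preset ufp_default --seed 42 --out campaign/
mobilegam fit --model ar --pollutant ufp --data campaign/ --out fit/
mobilegam sensitivity --suite wind --pollutant ufp --data campaign/ --out sens/
```

`fit/` contains `coefficients.csv` (estimate / lo95 / hi95 / p per term),
`curves.csv` (distance grids with 95% bands), `ar.json` and a QC report.
All coordinates are planar UTM meters; project lon/lat inputs first.

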