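# lynxkill

Kill-rate estimation and spatial predation-risk modelling for GPS-collared
Eurasian lynx (*Lynx lynx*) preying on roe deer (*Capreolus capreolus*) and
red deer (*Cervus elaphus*).

Telemetry-based predation studies reconstruct, for each collared lynx, a
*kill series*: the sequence of carcasses found at clusters of night GPS
positions.  From it they derive the **handling time** (nights spent at a
carcass), the **searching time** (from leaving one carcass to the next
kill), and their sum, the **prey time** — the inter-kill interval.  This
package implements the full analysis chain for such data, plus a synthetic
data generator with the same statistical structure, for wildlife ecologists
and quantitative conservation scientists:

- **killseries** — prey intervals from kill records (virtual kills reset
  the searching clock), winter/summer labelling (1 Nov – 31 Mar winter),
  species-specific right censoring (prey time > 9 d roe, > 12 d red), and
  kill-site detection from night-fix clusters;
- **aftmodel** — right-censored accelerated failure time regression
  `log T = x'β + σW` (Weibull or log-normal) of prey / handling / searching
  time on lynx status, prey species and season, with Tukey all-pair status
  contrasts and likelihood-ratio screening of interactions;
- **killrate** — parametric-bootstrap renewal kill counts per 365 or
  182.5 days, the actual-rate formula
  `rate = 365 · (share% / 100) / prey time`, per-km² predation pressure
  (rate / mean 95% MCP area), and cross-study recalculations;
- **homerange** — percentile minimum convex polygon home ranges and the
  study-area union;
- **spatialrisk** — a two-stage (hurdle) penalized-spline model of kill
  risk on a 500 m quadrant grid: logistic presence × zero-truncated
  Poisson abundance, combined as `expected = p̂ · μ̂`, with partial-risk
  surfaces and protected-area zone comparisons;
- **synthio** — synthetic landscapes, kill processes and collar schedules
  emulating the assumed data-generating structure;
- **pipeline** — end-to-end orchestration with a JSON run log, and a
  `lynxkill` command-line interface.

Model-shaped components are scikit-learn style estimators
(`AFTRegressor`, `PresenceGAM`, `TruncatedPoissonGAM`,
`MinimumConvexPolygon`) with `fit`/`predict` and underscored fitted
attributes; the module-level functions documented above are thin wrappers.

## Worked example

```python
from lynxkill import killrate, synthio, killseries, aftmodel

# Actual annual kill rate of a single adult female on roe deer, from a
# mean prey time of 6.71 d and a 92.31% roe-deer share of her kill series:
rate = killrate.actual_rate(prey_time=6.71, share_pct=92.31)
pressure = killrate.per_area_rate(rate, 122.0)   # mean female MCP, km²

# A censored AFT fit on a simulated 540-day study of nine lynx:
cfg = synthio.SimConfig(seed=1, monitoring_days=540)
kills = synthio.simulate_killseries(cfg, synthio.make_landscape(cfg))
intervals = killseries.censor_intervals(killseries.build_intervals(kills))
fit = aftmodel.fit_aft(intervals, aftmodel.AftSpec(distribution="lognormal"))
est = killrate.bootstrap_rate(
    fit, {"status": "family_group", "species": "roe", "season": "winter"},
    horizon=182.5, n_boot=5000, seed=1)
```

This prints (via the obvious `print` calls):

```
adult female roe-deer kill rate: 50.21 deer/year
predation pressure: 0.41 deer/year/km2
                  term  effect    se      z     p
             intercept   2.725 0.105 25.867 0.000
     status_adult_male  -0.256 0.080 -3.205 0.001
   status_family_group  -0.366 0.081 -4.525 0.000
status_subadult_female  -0.114 0.085 -1.343 0.179
           species_roe  -0.605 0.090 -6.754 0.000
         season_winter  -0.270 0.056 -4.803 0.000
family-group winter roe kills / 182.5 d: 33 (95% CI 25-41)
```

The 50.21 roe deer/year is the formula rate for an average single adult
female; 0.41 deer/year/km² is that rate spread over her mean 95% MCP home
range.  The negative coefficients mean shorter inter-kill times (faster
killing) for roe deer vs red deer, winter vs summer, and family groups
(females with two kittens) vs single females; the bootstrap turns the
fitted inter-kill distribution into a seasonal kill count with percentile
confidence bounds.

A full simulated-data run, writing `intervals.csv`, `aft_summary.csv`,
`rates.csv`, `homeranges.csv`, `risk.csv`, `zones.csv` and `run.json`:

```sh
lynxkill --seed 1 --outdir out run-all --n-boot 1000
```

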