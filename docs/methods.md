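# Methods

This note records the models, defaults and numerical choices behind
`lynxkill`, and what the synthetic-data generator does and does not
emulate.

## Kill series

A kill record carries the animal, its demographic status at the time
(adult male, single adult female, subadult female, or family group — a
female with two kittens; sparse classes such as juveniles, subadult males
and one-kitten family groups are excluded from analysis sets), the prey
species, the kill date, the date the carcass was left, coordinates, and a
found/virtual flag.  A *virtual kill* is a night-position cluster
consistent with a kill at which no carcass was found; it resets the
searching clock but is excluded from species-share summaries, and any
interval with a virtual endpoint is flagged `involves_virtual`.

For consecutive kills of one animal, handling time is the span from kill
to departure (nights at the carcass), searching time runs from departure
to the next kill, and prey time is their sum; the identity
`prey = handling + searching` holds exactly on every emitted interval
because the sum is computed, not re-derived.  Intervals are attributed to
the earlier (focal) kill: its species, its status, and the season of its
kill date.  Winter is 1 November – 31 March (151 days, 152 in leap years);
summer the remaining 214.  Intervals overlapping a declared collar gap are
dropped.  An interval whose *predecessor* is virtual is emitted and
flagged rather than dropped, since only its searching origin — not its
duration — involves the virtual record.

Censoring guards against unrecognized intervening kills: a prey time
strictly longer than 9 days (roe deer) or 12 days (red deer) is kept at
its observed duration with `event = False`.  "Longer than" is strict, so a
prey time exactly at the threshold is an event.  Because the censored
rows retain their realized durations (they are not truncated to the
threshold), the survival term of the likelihood is evaluated at values
that themselves depend on the outcome; recovery simulations show this
convention mildly inflates the estimated scale and intercept relative to
the generating process.  It is retained deliberately as the standard
encoding of this screening rule.

Kill-site detection groups night fixes (18:00–08:00 local, configurable)
by single linkage at a 200 m radius per animal; a site needs at least two
member fixes, its handling-night count is the number of distinct nights
contributing a fix, and its location is the member centroid.  These
operational constants stand in for an external field protocol and are all
configurable.

## Censored AFT regression

Prey, handling or searching time is modelled as
`log T = x'β + σW`, with `W` standard Gumbel-minimum (Weibull) or
standard normal (log-normal).  Events contribute the log-density, censored
rows the log-survival, of `log T`.  Covariates are treatment-coded factors
with reference levels single adult female / red deer / summer, so negative
coefficients mean faster killing.  The default family is Weibull — the
common AFT default, as the error family is not identified by the data
conventions above — with log-normal selectable everywhere; pairwise
`species:season`-style interactions are supported for likelihood-ratio
screening.  Per-animal frailty terms are out of scope.

Fitting maximizes the censored likelihood over `(β, log σ)` by BFGS with
analytic gradients (tolerance 1e-8, 500 iterations max, least-squares
start values); the covariance is the inverse of a central-difference
Hessian of the negative log-likelihood.  Factor levels with fewer than two
events raise a warning rather than being dropped.  Fitted means are
`exp(μ + σ²/2)` (log-normal) or `exp(μ)Γ(1+σ)` (Weibull); the median is
exposed as an option because summaries of this kind are sometimes
reported either way.

Tukey all-pair status contrasts use the single-step max-|z| adjustment:
all pairwise differences with their joint normal correlation (from the
fitted covariance), integrated by fixed-seed Monte Carlo (200,000 draws by
default; MC error on p is about ±0.002).

## Kill rates

The *predicted* rate is a parametric bootstrap: per replicate, draw
consecutive inter-kill times from the fitted distribution at one covariate
setting and count the intervals whose cumulative sum stays within the
horizon (365 d annual, 182.5 d seasonal); report the median and the
2.5/97.5 percentiles over 5,000 replicates.  Counting "within" the horizon
is the default; the alternative count-the-crossing rule is selectable, as
is a nonparametric mode resampling observed per-stratum prey times — the
published procedure does not pin either choice down.  For annual
predictions from a seasonal model the pipeline mixes seasons by their
calendar shares (214/365 summer).

The *actual* rate is `horizon · (share% / 100) / prey time`, scaling the
single-species renewal rate by the species' observed share of the status'
kill series.  Dividing by the mean male or female 95% MCP area gives
predation pressure in kills/year/km²; rates of overlapping territories
add.  Cross-study recalculations accept either (mean prey time, share) or
(kills, per-days) inputs.  Report rounding follows convention: rates to
2 dp, small per-km² red-deer rates to 3 dp.

## Home ranges

The percentile MCP removes the `⌈(1−level)·n⌉` fixes farthest from the
arithmetic centroid of all fixes — computed once, no re-centering, ties
broken by input order — and takes the convex hull of the rest (area via
the hull polygon, m² → km²).  The ceiling rule and fixed centroid are the
classical convention.  The study area is the union of individual hulls;
zone overlap fractions are computed against the quadrant grid's
protected-area cells.

## Two-stage spatial risk model

Kill counts on 500×500 m quadrants are zero-inflated, so each season is
modelled in two stages: (1) penalized logistic regression of presence
(≥1 kill) on smooths of forest proportion, altitude, distance to
civilization, and a 2-D tensor smooth of the cell centroids; (2) a
zero-truncated Poisson model of the positive counts with the same smooths
minus distance to civilization.  Stage 2 is fitted on cells with at least
one *observed* kill (fitting on cells with predicted presence p̂ > 0.5 is
exposed as an option); plain Poisson is selectable.  The combined surface
`expected = p̂ · E[N | N ≥ 1]` is a unitless relative index.  The partial
risk recomputes both linear predictors with the spatial smooth's
coefficients zeroed, isolating covariate effects.

Smooths are cubic B-spline bases (k = 10 univariate; 6×6 tensor) with
second-difference penalties, sum-to-zero constraints absorbed by a null
space reparameterization, and covariates standardized before basis
construction.  Smoothing parameters (one per smooth) minimize GCV
`n·D/(n−edf)²` over a penalized-IRLS inner loop (Nelder-Mead on log λ,
λ ∈ [e⁻⁸, e¹²]).  Note the unpenalized null spaces: a univariate smooth
retains 1 effective df (its linear trend) and the tensor smooth 3 (its
bilinear trend) even at maximal smoothing.  Zero-truncated Poisson scoring
uses `E[Y] = λ/(1−e^{−λ})` with Fisher weights `λ·dE[Y]/dλ`; linear
predictors are clipped at ±12 for stability, which caps conditional means
rather than letting them diverge on all-ones counts.  These basis/penalty/
selection choices are package defaults standing in for an unspecified
modelling protocol, not reconstructions of one.

Zone comparisons report mean ± SE of the presence probability and of the
expected kills per km² (cell area 0.25 km²) inside vs outside the
protected area, plus the Pearson correlation of altitude with expected
risk.  Being derived from deterministic fits, they should be compared
qualitatively.

## Synthetic data generator

The generator exists so every stage can be validated end to end with
known truth.  It emulates: a landscape with a contiguous high-altitude
protected core, towns (distance-to-civilization zero points) outside it,
and forest cover that varies cell to cell but is deliberately independent
of altitude, so the protected and unprotected zones offer comparable
habitat; per-lynx log-normal inter-kill times with the status / species /
season structure of the default coefficient set (intercept 2.516 log-days
at the reference cell) and σ = 0.55 — a stand-in spread chosen to give
realistic variation around ~6-day means, not an estimate; status-specific
roe/red shares (0.751 / 0.923 / 0.957 / 0.967 roe for males, single
females, subadult females, family groups); winter kills pulled toward low
altitude by a softmax with bias 3 (bias 0 makes seasons indistinguishable)
and summer kills near-uniform over forested cells; a 30% carcass miss rate
producing virtual kills, of the order seen in field prey datasets; a
handling fraction drawn as Beta(4, 3) of prey time; and a collar schedule
of midnight and midday fixes on a correlated random walk with midnight
fixes relocated to within 100 m of the active kill site on handling
nights.

It does *not* emulate: territoriality or any home-range structure in the
movement model (MCPs of the random walk are meaningful geometry but not
realistic sizes), prey depletion or density feedbacks, per-individual
frailty, collar failures and gaps, dusk/dawn intensive schedules, or
observation error in carcass dating.  Passing tests therefore demonstrate
the estimators recover the structure they assume — not that real
telemetry meets those assumptions.

All randomness derives from one seed through per-lynx child streams, so
equal configurations give byte-identical outputs.

## Problem sizes and determinism

Simulation-based tests use desk-scale versions of each design: grids of
20×20 to 30×30 cells, studies of 9–12 lynx over 1–2.5 years (roughly
1,500 intervals for parameter recovery), 5,000 bootstrap replicates, and
250 replications for null-distribution calibration of the likelihood-ratio
test at n = 300 rows (chi-square calibration is visibly anti-conservative
below ~150 rows, a finite-sample property, not a defect).  Every stochastic
test and the pipeline itself are seeded; reruns are bit-identical.

## Known limitations

Field-scale quantities that depend on the original telemetry (fitted
coefficient values, predicted-rate confidence bounds, absolute zone means
and altitude correlations) are not reproducible from synthetic data and
are validated structurally instead.  The AFT error family and the exact
spatial-model protocol are package choices; both are configurable and
documented above.  The hurdle model's conditional-count stage
extrapolates beyond the covariate range of the positive cells when
predicting on the full grid; predictions there are clamped to the
training basis range.
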