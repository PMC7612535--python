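# Methods

## Problem

Public-health agencies monitor the mortality burden of heatwaves in near
real time. Two estimator families are in use: *excess deaths* — observed
minus expected deaths summed over a heatwave, with the expectation built
from the same summer's non-heatwave days — and *attributable deaths* — a
temperature–mortality association estimated from historical summers,
applied to current temperatures. The package implements both against a
common data model (daily death counts and daily mean temperatures per
region, a Central-England-Temperature-like series, heat-alert days) so
they can be compared period by period and year by year.

## Heatwave definition

A day qualifies if a Level-3-style heat alert was in force or the CET-like
series exceeds `cet_threshold` (default 20 °C, strict inequality). Maximal
runs of consecutive qualifying days form raw periods; each is extended by
`extension_days` (default 1) on both sides. Two design points:

* When extended intervals of two distinct raw runs touch or overlap (one
  cool day between two hot spells), the runs are **not merged**; the later
  period's start is clipped one day past the earlier period's end, so the
  shared day is counted once, in the earlier period.
* Extension is applied after run detection, not to individual qualifying
  days; a 1-day run therefore becomes a 3-day period.
* Missing days inside the CET span are rejected, not imputed — the
  criterion is a hard daily threshold. Officially published periods can be
  loaded verbatim (`load_configured_heatwaves`) and override detection;
  because published period lists do not state whether bounds already
  include the ±1-day extension, both raw and extended bounds are carried
  and configuration selects which one downstream sums use.

## Excess-death estimator

For baseline period `[b0, b1]` (conventionally 1 May – 30 Sep):

* `linear_trend`: OLS of deaths on integer day index over all non-heatwave
  baseline days (non-heatwave judged by **extended** bounds, so extension
  days never contaminate the baseline), evaluated on every baseline day.
* `window_mean`: per heatwave, the mean of the nearest
  `window_half_width = 7` non-heatwave days strictly before and strictly
  after (14 days total) — the pandemic-season variant.

Excess over a period of length `L` is `Σ (observed − expected)`; the 95%
interval is `±1.96·s·√L`, with `s` the sample SD of non-heatwave baseline
deaths. The exact operational interval construction is not published in a
reproducible form; treating the period sum as an L-fold accumulation of
day-level noise with SD `s` is the natural reading of "based on the
standard deviation of deaths on non-heatwave days" and is exposed as a
pluggable choice (`z` parameter; the formula lives in one place,
`excess_deaths`). Estimates from strata or regions are pooled by summing
centrals and combining interval halfwidths in quadrature (upper and lower
separately). Periods whose ±1-day extension crosses the baseline boundary
are clipped to it — there are no observations beyond the baseline.

Known property: a linear baseline cannot represent within-summer
curvature; with a U-shaped seasonal mortality profile the mid-summer
baseline is overestimated and heatwave excess biased down. This is a
property of the method under study, deliberately reproduced, not
corrected.

## Distributed-lag non-linear model

Counts `n_t` are modelled as quasi-Poisson with log link. The design is:

* **Cross-basis**: natural cubic spline of temperature, internal knots at
  the 50th/90th percentiles of the pooled training-summer temperatures,
  boundary knots at the pooled min/max — 3 columns, each evaluated at lags
  0..3 (unconstrained lag dimension) — 12 columns. The truncated-power
  natural-spline construction makes every column exactly linear at and
  beyond the boundary knots, so the curve extrapolates log-linearly to
  unseen temperatures.
* **Confounders**: day-of-week indicators (reference Monday), a 4-df
  day-of-year natural spline (knots at day-of-year quantiles), year
  indicators (reference: first training year), and day-of-year × year
  interactions. With 10 training summers: 1 + 6 + 4 + 9 + 36 + 12 = 68
  columns for 1530 modelled days.

Fitting is by iteratively reweighted least squares initialised at
`log(mean(y))` for the intercept, zeros elsewhere; convergence when the
max coefficient step falls below `1e-9` (relative), at most 100
iterations; rank deficiency is detected by pivoted QR and reported by
column name. The linear predictor is clamped to ±30 as an overflow guard
(irrelevant at mortality scales, where it is ≈5). Dispersion is Pearson
`X²/(n − p)` and scales the covariance `φ·(XᵀWX)⁻¹`.

Days lacking a full lag-0..3 temperature history are dropped from the
likelihood; when lead-in days before 1 May are supplied (the synthetic
generator provides 3 per block), nothing is dropped and no exposure is
fabricated.

**Cumulative association and MMT.** Summing the cross-basis coefficients
over lags gives the cumulative log-RR curve. The MMT is its argmin on a
0.1 °C grid over [P50 of training temperatures, training maximum] — the
lower bound encodes the prior that the optimum lies above the median
summer temperature, the upper bound is the training maximum (an upper
percentile bound would also be defensible; the maximum was chosen so the
search interval needs no extra tuning constant). Ties break toward the
lower temperature; the curve is centred to zero at the MMT. Training
windows follow the "ten preceding summers" convention, with arbitrary
windows expressible in the pipeline config (e.g. a 2009–2018 window for a
2020 target).

## Attribution

Backward perspective with same-day observed deaths:
`AN_t = n_t · (1 − exp(−c(x_t)))` on days with `x_t >` MMT, zero
otherwise. A config option substitutes model-predicted baseline deaths for
`n_t` for true near-real-time use. Period totals sum daily values over
each heatwave (an option reports whole-summer totals instead — the period
wording "sum all heat-related deaths in each region and heatwave" is
ambiguous between the two, so both are available and the per-heatwave
restriction is the default).

Uncertainty: 100 draws of the cross-basis coefficient block from a
multivariate normal with the fitted mean and dispersion-scaled covariance;
the centred curve and period totals are recomputed per draw with the MMT
held at its central estimate (re-estimating the centering point per draw
is deliberately not done — the simulation is of association coefficients,
not of the optimum); the 95% interval is the empirical 2.5–97.5 percentile
range (linear interpolation), with the point-estimate total reported as
the central value and the interval widened to include it when n_mc is
small enough for the percentiles to exclude it. Negative per-draw totals
(possible under sampled coefficients, and for temperatures beyond the MMT
search interval where the centred curve may dip below zero under
extrapolation) are retained, not clipped. A covariance with eigenvalues
below −1e−8 of the spectral radius is rejected with a pointer to
eigenvalue clipping; tiny negative eigenvalues from round-off are handled
by the eigendecomposition sampler.

## Estimator comparison

Paired (region × heatwave) estimates are summarised by an
orthogonal-distance (total least squares) line: the principal axis of the
centred point cloud, appropriate because both axes are deaths with
comparable error; per-point weights from the interval widths are available
but off by default since the published comparison states none. Annual
national totals sum centrals and combine intervals in quadrature; when
per-draw attribution totals are available the total's interval is instead
computed exactly by summing within each draw (draws are independent across
regions). Agreement is flagged as "method A's central inside method B's
95% interval", plus a separate interval-overlap flag.

## Synthetic-data generator

Temperature per region: seasonal sinusoid (base 12.5 °C, amplitude
5.5 °C, peak mid-July) + stationary AR(1) noise (coefficient 0.65,
innovation SD 1.6 °C) + configured heat episodes (defaults: +4 °C for 5
days from 10 July, +3 °C for 3 days from 9 August, every summer). Each
153-day block carries 3 lead-in days so every modelled day has a full lag
history. The CET-like series is a weighted regional average plus noise
(SD 0.3 °C); alert days are exactly the episode days.

Deaths: mean `μ_t = baseline · dow · season · year ·
exp(Σ_ℓ w_ℓ · β · max(0, x_{t−ℓ} − MMT*))` with baseline 120 deaths/day
(a mid-sized English region), mild day-of-week factors, a winter-peaking
seasonal cosine (log-amplitude 0.06, so mortality dips ~5% mid-summer),
per-summer year factors, lag weights (0.4, 0.3, 0.2, 0.1) over lags 0–3,
`β = ln(1.05)` per °C and `MMT* = 17 °C` (≈65th percentile of the
simulated summer distribution; observational studies for England place
the optimum around the 73rd–79th). Counts are gamma-mixed Poisson with
variance `φ·μ` (φ = 1.3), matching the quasi-Poisson variance function at
the first two moments. The truth record stores `μ_t` and the per-day
attributable expectation `μ_t(1 − exp(−c_t))`, which sums to the quantity
attribution should recover in expectation. A `null_config` preset (β = 0,
flat day-of-week/season/year) supports calibration checks. All streams
derive from `(seed, region, purpose)` so runs are bit-reproducible.

What the generator does **not** emulate: population ageing and
denominators, spatial correlation beyond the shared CET construction,
registration delays, reporting artefacts, co-circulating shocks
(epidemics), and temperature measurement error. Passing tests therefore
demonstrate internal statistical correctness of the estimators under a
known data-generating process, not robustness to those real-data
features.

## Numerical choices

Dates ISO-8601, intervals closed on both ends; temperatures carried at
0.1 °C; MMT grid 0.1 °C (finer than the inputs); IRLS tolerance 1e-9;
percentiles via linear interpolation; Monte Carlo n = 100 by default;
ties in the MMT search break toward the colder temperature; reference
levels Monday / first training year.

## Problem sizes used in the checks

The statistical checks run at the study's natural scale: 10 training
summers (1530 days, 68 parameters) per fit; 50 simulation seeds for
recovery and coverage rates; 100 seeds for null calibration; 100 Monte
Carlo draws per interval; a two-region study for the end-to-end
comparison.

## Known limitations

* **Spline-vs-kink smoothing bias.** The generator's cumulative risk
  curve has a kink at the optimum; a 3-df natural spline with knots at
  P50/P90 cannot represent a kink (cubic splines are C²), and the
  maximum-likelihood fit smooths through it, undershooting cumulative
  log-RR by ≈0.02 across 18–24 °C. Summer attributable totals are
  consequently biased ≈10% low under the default conditions, while the
  Monte Carlo interval reflects only coefficient uncertainty — so the
  interval's coverage of the generator truth is well below nominal. This
  is a faithful property of the estimator design, documented rather than
  patched; with a smooth generative curve (or wider intervals that
  propagate observation noise and MMT uncertainty) coverage improves.
* **Null-attribution positivity.** Centring at the in-sample argmin makes
  the centred curve non-negative on warm days, so central attributable
  totals are ≥ 0 by construction; under a zero-effect null the mean
  attributable total is a small positive number (~12 deaths per summer,
  0.07% of summer deaths, under the default conditions), not zero. The
  excess estimator, being signed, is mean-unbiased under the same null.
* The excess estimator's interval treats day-level noise as independent
  (no autocorrelation) and its baseline as noise-free.
* Attribution applies the cumulative curve to the same-day temperature
  (standard backward perspective); it redistributes no deaths across
  future days and is not a harvesting analysis.
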