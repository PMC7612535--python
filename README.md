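# heatmort

Estimators of the mortality burden of heatwaves from regional daily death
counts and daily mean temperatures, built for public-health mortality
monitoring and for studying how two widely used approaches disagree:

* **Surveillance-style excess deaths** (`UKHSAExcess`): expected (baseline)
  deaths are a linear trend fitted to all non-heatwave days of a summer
  baseline period (or, for pandemic seasons, the mean of the seven
  non-heatwave days flanking each heatwave); heatwave excess is the
  cumulative observed − expected difference, with a 95% interval scaled
  from the day-to-day SD of non-heatwave deaths,
  `±1.96·s·√L` for an `L`-day period.
* **DLNM heat attribution** (`DLNMHeatModel`): a quasi-Poisson
  distributed-lag non-linear model. The exposure–response is a natural
  cubic spline of daily mean temperature with internal knots at the 50th
  and 90th percentiles of the pooled training-summer temperatures (boundary
  knots at the pooled min/max, hence log-linear extrapolation), crossed
  with an unconstrained lag basis over lags 0–3 (3 spline × 4 lag = 12
  cross-basis columns). Confounders: day-of-week indicators, a 4-df
  day-of-year natural spline, year indicators, and their interaction.
  Summing cross-basis coefficients over lags gives the cumulative
  log-relative-risk curve `c(x)`; its argmin over [P50, training max] is
  the minimum mortality temperature (MMT), and the curve is centred there.
  On each warm day (`x_t > MMT`) the attributable number is
  `AN_t = n_t · (1 − exp(−c(x_t)))`; 95% intervals come from 100
  multivariate-normal draws of the cross-basis coefficients.

Heatwave periods follow the operational public-health definition: days with
a heat-health alert in force *or* mean Central England Temperature above
20 °C, in maximal consecutive runs, extended by one day on either side.

A synthetic-data generator (`heatmort.simulate`) produces regional summer
series (1 May – 30 Sep blocks) with a known optimum temperature, a known
cumulative risk slope distributed over lags 0–3, day-of-week/season/year
structure and overdispersed counts — with per-day bookkept truth — so the
whole pipeline is testable without any data downloads. The comparison
module summarises paired estimates with an orthogonal-distance (total
least squares) best-fit line and interval-agreement flags.

## Worked example

Simulate one region (11 summers: 10 training + 1 target, ~120 deaths/day,
cumulative RR 1.05 per °C above a 17 °C optimum), fit the association on
2001–2010, detect 2011 heatwaves, and run both estimators:

```python
import heatmort as hm

cfg = hm.default_config(n_summers=11, region_names=("North",), seed=3)
study = hm.simulate_study(cfg)
region = study.regions["North"]

model = hm.DLNMHeatModel().fit(region.temperatures,
                               region.deaths.loc[:"2010-12-31"])
start, end = hm.summer_span(2011)
crit = hm.HeatwaveCriteria(
    alert_days=frozenset(d for d in study.alert_days if d.year == 2011))
heatwaves = [p.clip_to(start, end)
             for p in hm.identify_heatwaves(study.cet.loc[start:end], crit)]

target = region.deaths.loc[start:end]
dlnm = hm.monte_carlo_ci(model.association_, region.temperatures, target,
                         heatwaves, n_mc=100, seed=1, region="North")
ukhsa = hm.UKHSAExcess().fit(target, heatwaves, baseline=(start, end))
```

Output (abridged):

```
dispersion 1.34, MMT 16.9 C (true optimum 17.0 C)
log-RR slope above MMT 0.0500 (true 0.0488)
9 heatwaves detected in 2011
2011-07-09 to 2011-07-15: DLNM 135.3 (124.2 to 146.0)  excess 101.7 (36.2 to 167.3)
2011-08-07 to 2011-08-12: DLNM 122.2 (112.4 to 131.4)  excess 114.1 (53.4 to 174.8)
...
summer totals: DLNM 566, excess 386, truth 561
```

The fitted dispersion reflects the generator's overdispersion (1.3), the
recovered optimum and risk slope sit on top of the generative values, and
the attributable total tracks the bookkept truth. The excess estimator
reads lower here because each short period mixes lagged heat deaths into
neighbouring baseline days — exactly the disagreement pattern the
comparison module is built to quantify.

The same steps are available from the shell:

```sh
heatmort simulate --outdir data --seed 3
heatmort heatwaves --cet data/cet.csv --alerts data/alerts.csv --out hw.csv
heatmort dlnm-fit --deaths data/deaths.csv --temps data/temperatures.csv \
    --region North --train-start 2001 --train-end 2010 --out model.json
heatmort attribute --model model.json --temps data/temperatures.csv \
    --deaths data/deaths.csv --region North --heatwaves hw.csv --out an.csv
heatmort run --config pipeline.yaml --outdir results   # full comparison
```

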