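import numpy as np
import pandas as pd
import pytest

import heatmort as hm
from heatmort.dlnm import SplineBasis


def _linear_association(slope=0.1, var=0.0, mmt=0.0):
    """Single linear exposure column, lag 0: c(x) = slope·x, centred at mmt."""
    return hm.FittedAssociation(
        coef=np.array([slope]),
        cov=np.array([[var]]),
        dispersion=1.0,
        column_names=["cb_s0_l0"],
        crossbasis_index=np.array([0]),
        basis=SplineBasis((), (0.0, 10.0)),
        max_lag=0,
        mmt=mmt,
        training_percentiles={0.0: 0.0, 50.0: 5.0, 100.0: 10.0},
    )


def _days(values, start="2011-07-01"):
    return pd.Series(list(values), index=pd.date_range(start, periods=len(values)))


def test_no_attribution_at_or_below_mmt():
    a = _linear_association(slope=0.2, mmt=3.0)
    temps = _days([3.0, 2.0, 1.0])
    deaths = _days([100, 100, 100])
    an = hm.daily_attributable(a, temps, deaths)
    assert (an == 0).all()


def test_relative_risk_two_attributes_half():
    # centred log-RR = log 2 on the warm day ⇒ AN = n/2
    a = _linear_association(slope=np.log(2.0), mmt=0.0)
    temps = _days([1.0])
    deaths = _days([100])
    an = hm.daily_attributable(a, temps, deaths)
    assert an.iloc[0] == pytest.approx(50.0)


def test_missing_deaths_on_warm_day_rejected():
    a = _linear_association(slope=0.1, mmt=0.0)
    temps = _days([1.0, 1.0])
    deaths = _days([100.0, np.nan])
    with pytest.raises(ValueError):
        hm.daily_attributable(a, temps, deaths)


def test_period_total_matches_loop_sum():
    rng = np.random.default_rng(2)
    daily = _days(rng.uniform(0, 5, 30))
    period = hm.HeatwavePeriod(
        daily.index[4], daily.index[18], daily.index[4], daily.index[18], "configured"
    )
    total = hm.period_total(daily, period)
    looped = sum(daily.iloc[i] for i in range(4, 19))
    assert total == pytest.approx(looped)
    with pytest.raises(ValueError, match="span"):
        hm.period_total(daily, hm.HeatwavePeriod(
            daily.index[0] - pd.Timedelta(days=1), daily.index[3],
            daily.index[0] - pd.Timedelta(days=1), daily.index[3], "configured"))


def test_totals_add_over_disjoint_periods():
    rng = np.random.default_rng(3)
    daily = _days(rng.uniform(0, 5, 40))
    p1 = hm.HeatwavePeriod(daily.index[2], daily.index[9], daily.index[2], daily.index[9], "cet")
    p2 = hm.HeatwavePeriod(daily.index[20], daily.index[29], daily.index[20], daily.index[29], "cet")
    union = hm.HeatwavePeriod(daily.index[2], daily.index[29], daily.index[2], daily.index[29], "cet")
    gap = daily.iloc[10:20].sum()
    assert hm.period_total(daily, p1) + hm.period_total(daily, p2) == pytest.approx(
        hm.period_total(daily, union) - gap
    )


def test_zero_covariance_collapses_interval():
    a = _linear_association(slope=0.1, var=0.0, mmt=0.0)
    temps = _days([2.0, 3.0, 1.0, 0.5])
    deaths = _days([100, 120, 90, 80])
    period = hm.HeatwavePeriod(temps.index[0], temps.index[-1],
                               temps.index[0], temps.index[-1], "configured")
    (est,) = hm.monte_carlo_ci(a, temps, deaths, [period], n_mc=50, seed=0)
    assert est.ci_low == pytest.approx(est.central)
    assert est.ci_high == pytest.approx(est.central)


def test_same_seed_reproduces_interval(fitted_model, north, target_deaths):
    period = hm.HeatwavePeriod(
        pd.Timestamp("2011-07-10"), pd.Timestamp("2011-07-16"),
        pd.Timestamp("2011-07-11"), pd.Timestamp("2011-07-15"), "cet")
    kw = dict(n_mc=60, seed=123)
    (a,) = hm.monte_carlo_ci(fitted_model.association_, north.temperatures,
                             target_deaths, [period], **kw)
    (b,) = hm.monte_carlo_ci(fitted_model.association_, north.temperatures,
                             target_deaths, [period], **kw)
    assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


def test_interval_matches_delta_method_on_linear_toy():
    # one coefficient, monotone total: empirical quantiles of the simulated
    # total must match the transformed normal-theory endpoints
    slope, sd = 0.08, 0.01
    a = _linear_association(slope=slope, var=sd**2, mmt=0.0)
    rng = np.random.default_rng(0)
    temps = _days(rng.uniform(0.5, 6.0, 60))
    deaths = _days(rng.poisson(100, 60))
    period = hm.HeatwavePeriod(temps.index[0], temps.index[-1],
                               temps.index[0], temps.index[-1], "configured")
    (est,) = hm.monte_carlo_ci(a, temps, deaths, [period], n_mc=10_000, seed=4)

    def total(beta):
        return float((deaths.to_numpy() * (1 - np.exp(-beta * temps.to_numpy()))).sum())

    lo = total(slope - 1.959963984540054 * sd)
    hi = total(slope + 1.959963984540054 * sd)
    assert est.ci_low == pytest.approx(lo, rel=0.02)
    assert est.ci_high == pytest.approx(hi, rel=0.02)


def test_non_psd_covariance_rejected():
    a = _linear_association(slope=0.1, var=-1.0, mmt=0.0)
    temps = _days([2.0])
    deaths = _days([100])
    period = hm.HeatwavePeriod(temps.index[0], temps.index[0],
                               temps.index[0], temps.index[0], "configured")
    with pytest.raises(np.linalg.LinAlgError, match="eigenvalue"):
        hm.monte_carlo_ci(a, temps, deaths, [period], n_mc=10, seed=0)


def test_central_attribution_nonnegative_on_warm_days(fitted_model, north, target_deaths):
    # the centred minimum lies at the MMT inside the search interval, so
    # central warm-day attribution cannot be negative (beyond tolerance)
    daily = hm.daily_attributable(fitted_model.association_, north.temperatures, target_deaths)
    assert (daily >= -1e-9).all()
    x = north.temperatures.reindex(target_deaths.index)
    assert (daily[x <= fitted_model.mmt_] == 0).all()


def test_attribute_wrapper_bundles_everything(fitted_model, north, target_deaths):
    period = hm.HeatwavePeriod(
        pd.Timestamp("2011-07-10"), pd.Timestamp("2011-07-16"),
        pd.Timestamp("2011-07-11"), pd.Timestamp("2011-07-15"), "cet")
    res = hm.attribute(fitted_model.association_, north.temperatures,
                       target_deaths, [period], n_mc=40, seed=9, region="North")
    assert res.n_mc == 40
    (est,) = res.period_totals
    assert est.central == pytest.approx(hm.period_total(res.daily, period))
    assert est.region == "North" and est.method == "dlnm"
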