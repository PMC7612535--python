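import numpy as np
import pandas as pd
import pytest
from scipy import linalg
from scipy.optimize import minimize

import heatmort as hm
from heatmort.dlnm import SplineBasis, build_covariates, find_mmt


# ---------------------------------------------------------------------------
# natural spline basis
# ---------------------------------------------------------------------------

def test_basis_column_count_is_internal_knots_plus_one():
    x = np.linspace(0, 30, 50)
    b = hm.natural_spline_basis(x, (16, 20), (10, 26))
    assert b.shape == (50, 3)
    b1 = hm.natural_spline_basis(x, (15, 18, 21), (10, 26))
    assert b1.shape == (50, 4)


def test_basis_linear_beyond_boundaries():
    basis = SplineBasis((16.0, 20.0), (10.0, 26.0))
    # above the upper boundary: equal steps give equal increments
    x = np.array([27.0, 28.0, 29.0])
    vals = basis(x)
    np.testing.assert_allclose(vals[2] - vals[1], vals[1] - vals[0], atol=1e-9)
    # below the lower boundary too
    x = np.array([5.0, 6.0, 7.0])
    vals = basis(x)
    np.testing.assert_allclose(vals[2] - vals[1], vals[1] - vals[0], atol=1e-9)


def test_basis_second_difference_vanishes_beyond_boundary():
    basis = SplineBasis((16.0, 20.0), (10.0, 26.0))
    h = 0.05

    def second_diff(x0):
        pts = basis(np.array([x0 - h, x0, x0 + h]))
        return (pts[0] - 2 * pts[1] + pts[2]) / h**2

    inside = np.abs(second_diff(18.0))
    beyond = np.abs(second_diff(27.0))
    assert np.all(beyond < 1e-8)
    assert inside.max() > 1e-3  # genuinely curved inside


def test_coincident_knots_rejected():
    with pytest.raises(ValueError, match="increasing"):
        hm.natural_spline_basis(np.arange(5.0), (16, 16), (10, 26))
    with pytest.raises(ValueError, match="bracket"):
        SplineBasis((9.0, 20.0), (10.0, 26.0))


# ---------------------------------------------------------------------------
# cross-basis
# ---------------------------------------------------------------------------

def _temps(values, start="2001-05-01"):
    return pd.Series(
        list(values), index=pd.date_range(start, periods=len(values)), dtype=float
    )


def test_constant_series_gives_identical_rows():
    basis = SplineBasis((16.0, 20.0), (10.0, 26.0))
    temps = _temps([18.0] * 12)
    X, valid = hm.build_cross_basis(temps, basis, max_lag=3)
    rows = X.to_numpy()[valid]
    assert np.allclose(rows, rows[0])
    assert valid.sum() == 9  # first 3 days lack full history


def test_zero_lag_reduces_to_plain_basis():
    basis = SplineBasis((16.0, 20.0), (10.0, 26.0))
    temps = _temps(np.linspace(12, 24, 10))
    X, valid = hm.build_cross_basis(temps, basis, max_lag=0)
    assert valid.all()
    np.testing.assert_allclose(X.to_numpy(), basis(temps.to_numpy()))


def test_cross_basis_cells_match_direct_evaluation():
    rng = np.random.default_rng(1)
    basis = SplineBasis((16.0, 20.0), (10.0, 26.0))
    temps = _temps(rng.uniform(10, 26, 20))
    X, valid = hm.build_cross_basis(temps, basis, max_lag=3)
    t = 10
    row = X.iloc[t].to_numpy()
    expected = np.empty(12)
    for j in range(3):
        for lag in range(4):
            expected[j * 4 + lag] = basis(np.array([temps.iloc[t - lag]]))[0, j]
    np.testing.assert_allclose(row, expected)


# ---------------------------------------------------------------------------
# covariate design
# ---------------------------------------------------------------------------

def test_design_widths_for_ten_training_summers():
    dates = pd.DatetimeIndex(
        np.concatenate([hm.summer_index(y) for y in range(2001, 2011)])
    )
    C = build_covariates(dates)
    assert sum(c.startswith("dow_") for c in C.columns) == 6
    assert sum(c.startswith("doy_s") and ":" not in c for c in C.columns) == 4
    assert sum(c.startswith("year_") for c in C.columns) == 9
    assert sum(":" in c for c in C.columns) == 36
    assert C.shape[1] == 1 + 6 + 4 + 9 + 36


# ---------------------------------------------------------------------------
# quasi-Poisson IRLS
# ---------------------------------------------------------------------------

def test_intercept_only_closed_form():
    y = np.full(50, 7.0)
    res = hm.fit_quasipoisson(y, np.ones((50, 1)))
    assert res.coef[0] == pytest.approx(np.log(7.0), abs=1e-10)


def test_matches_independent_optimizer():
    rng = np.random.default_rng(42)
    X = np.column_stack([np.ones(200), rng.normal(scale=0.5, size=(200, 9))])
    beta = rng.normal(scale=0.2, size=10)
    beta[0] = 2.5
    y = rng.poisson(np.exp(X @ beta))
    res = hm.fit_quasipoisson(y, X)

    def nll(b):
        eta = X @ b
        return -(y @ eta - np.exp(eta).sum())

    opt = minimize(nll, np.zeros(10), method="BFGS", tol=1e-12)
    assert np.max(np.abs(res.coef - opt.x)) < 1e-6


def test_matches_statsmodels_glm():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(3)
    X = np.column_stack([np.ones(300), rng.normal(size=(300, 4))])
    y = rng.poisson(np.exp(X @ np.array([3.0, 0.2, -0.1, 0.05, 0.0])))
    res = hm.fit_quasipoisson(y, X)
    glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    np.testing.assert_allclose(res.coef, glm.params, atol=1e-8)
    phi = glm.pearson_chi2 / glm.df_resid
    np.testing.assert_allclose(res.cov, phi * glm.cov_params() / glm.scale, rtol=1e-6)


def test_poisson_dispersion_near_one():
    rng = np.random.default_rng(0)
    X = np.column_stack([np.ones(1530), rng.normal(size=(1530, 3))])
    y = rng.poisson(np.exp(X @ np.array([3.0, 0.1, -0.05, 0.02])))
    res = hm.fit_quasipoisson(y, X)
    assert 0.9 < res.dispersion < 1.1


def test_covariance_is_dispersion_times_inverse_information():
    rng = np.random.default_rng(5)
    X = np.column_stack([np.ones(150), rng.normal(size=(150, 2))])
    y = rng.poisson(np.exp(X @ np.array([2.0, 0.3, -0.2])) * rng.gamma(2.0, 0.5, 150))
    res = hm.fit_quasipoisson(y, X)
    info = (X.T * res.fitted) @ X
    np.testing.assert_allclose(res.cov, res.dispersion * linalg.inv(info), rtol=1e-8)
    # dispersion linearity: doubling phi doubles every variance
    np.testing.assert_allclose(
        2 * res.dispersion * linalg.inv(info), 2 * res.cov, rtol=1e-8
    )


def test_rank_deficiency_names_columns():
    X = pd.DataFrame(
        {"intercept": np.ones(30), "a": np.arange(30.0), "b": 2 * np.arange(30.0)}
    )
    y = np.random.default_rng(0).poisson(10, 30)
    with pytest.raises(np.linalg.LinAlgError, match="collinear"):
        hm.fit_quasipoisson(y, X)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        hm.fit_quasipoisson(np.array([1.0, -1.0, 2.0]), np.ones((3, 1)))


# ---------------------------------------------------------------------------
# cumulative association and MMT
# ---------------------------------------------------------------------------

def test_zero_coefficients_give_flat_curve(fitted_model):
    a = fitted_model.association_
    zero = np.zeros(len(a.crossbasis_index))
    np.testing.assert_allclose(a.cumulative_curve(np.linspace(12, 26, 20), zero), 0.0)


def test_cumulative_curve_decomposes_over_lags(fitted_model):
    a = fitted_model.association_
    grid = np.linspace(12, 26, 15)
    total = a.cumulative_curve(grid)
    # independent per-lag reconstruction
    cb = a.crossbasis_coef.reshape(a.basis.ncol, a.max_lag + 1)
    per_lag = np.zeros_like(total)
    for lag in range(a.max_lag + 1):
        per_lag += a.basis(grid) @ cb[:, lag]
    np.testing.assert_allclose(total, per_lag, rtol=1e-12)


def test_linear_exposure_sums_per_lag_slopes():
    # single linear exposure column, per-lag coefficients c0..c3
    basis = SplineBasis((), (0.0, 1.0))
    coef = np.array([0.1, 0.2, 0.3, 0.4])
    a = hm.FittedAssociation(
        coef=coef,
        cov=np.zeros((4, 4)),
        dispersion=1.0,
        column_names=[f"cb_s0_l{k}" for k in range(4)],
        crossbasis_index=np.arange(4),
        basis=basis,
        max_lag=3,
        mmt=0.0,
        training_percentiles={0.0: 0.0, 50.0: 0.5, 100.0: 1.0},
    )
    x = np.array([0.0, 1.0, 2.0])
    np.testing.assert_allclose(a.cumulative_curve(x), 1.0 * x)  # Σc = 1.0


def test_find_mmt_quadratic_minimum():
    mmt = find_mmt(lambda x: (np.asarray(x) - 19.3) ** 2, 16.0, 24.0, 0.1)
    assert abs(mmt - 19.3) <= 0.1 + 1e-9


def test_find_mmt_boundary_and_ties():
    assert find_mmt(lambda x: np.asarray(x) * 1.0, 16.0, 24.0) == pytest.approx(16.0)
    # flat curve: tie broken toward the lower temperature
    assert find_mmt(lambda x: np.zeros_like(np.asarray(x, float)), 16.0, 24.0) == pytest.approx(16.0)
    with pytest.raises(ValueError, match="degenerate"):
        find_mmt(lambda x: x, 24.0, 24.0)


def test_centered_curve_vanishes_at_mmt(fitted_model):
    a = fitted_model.association_
    assert a.centered_curve(np.array([a.mmt]))[0] == pytest.approx(0.0, abs=1e-12)
    assert a.mmt >= a.training_percentiles[50.0] - 1e-9


# ---------------------------------------------------------------------------
# full estimator
# ---------------------------------------------------------------------------

def test_fit_recovers_simulated_association(north, fitted_model):
    cfg_slope = np.log(1.05)
    a = fitted_model.association_
    slope = a.curve_slope_above_mmt()
    assert abs(slope - cfg_slope) / cfg_slope < 0.25
    assert abs(fitted_model.mmt_ - 17.0) < 1.5
    assert fitted_model.n_obs_ == 1530
    assert len(fitted_model.coef_) == 68
    assert fitted_model.dispersion_ > 1.0  # generator is overdispersed
    # covariance symmetric PSD
    w = np.linalg.eigvalsh(fitted_model.cov_)
    assert w.min() > -1e-10 * abs(w.max())


def test_missing_lag_history_rows_are_dropped(north):
    # strip the lead-in days: the first 3 days of each block leave the fit
    temps_inblock = north.temperatures[north.temperatures.index.month != 4]
    train = north.deaths.loc[:"2010-12-31"]
    m = hm.DLNMHeatModel().fit(temps_inblock, train)
    assert m.n_obs_ == 1530 - 3 * 10


def test_missing_modelled_day_temperature_rejected(north):
    train = north.deaths.loc[:"2002-12-31"]
    with pytest.raises(ValueError, match="missing"):
        hm.DLNMHeatModel().fit(north.temperatures.iloc[:100], train)
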