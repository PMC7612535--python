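"""Distributed-lag non-linear model of temperature and mortality.

The exposure–response dimension is a natural cubic spline of daily mean
temperature (two internal knots at the 50th and 90th percentiles of the
pooled training-summer temperatures, boundary knots at the pooled min/max;
natural splines extrapolate log-linearly beyond the boundaries).  The lag
dimension is unconstrained over lags 0..3 — one indicator per lag — so the
cross-basis is the spline basis evaluated at each lagged temperature,
3 spline columns × 4 lags = 12 columns.

Counts are fitted by quasi-Poisson regression (hand-rolled IRLS; the Pearson
statistic estimates the dispersion that scales the coefficient covariance)
with covariates controlling for day of week, a within-summer day-of-year
spline, year, and a day-of-year × year interaction.

Summing the cross-basis coefficients over lags gives the cumulative
log-relative-risk curve; its minimum over [P50 of training temperatures,
training maximum] is the minimum mortality temperature (MMT), and the curve
is centred there so that risk is expressed relative to the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator

from .series import check_daily, check_deaths

__all__ = [
    "natural_spline_basis",
    "SplineBasis",
    "CrossBasisSpec",
    "build_cross_basis",
    "build_covariates",
    "fit_quasipoisson",
    "QuasiPoissonResult",
    "FittedAssociation",
    "find_mmt",
    "DLNMHeatModel",
]


# ---------------------------------------------------------------------------
# natural cubic spline basis (truncated-power construction)
# ---------------------------------------------------------------------------

def natural_spline_basis(x, internal_knots, boundary_knots) -> np.ndarray:
    """Natural cubic spline basis, no intercept column.

    With K = 2 + len(internal_knots) knots the basis has K − 1 columns: the
    identity column ``x`` plus K − 2 truncated-power combinations whose
    cubic and quadratic terms cancel beyond the last knot, so every column
    is exactly linear outside the boundary knots (second derivative zero at
    and beyond them).
    """
    x = np.asarray(x, float)
    lo, hi = float(boundary_knots[0]), float(boundary_knots[1])
    knots = np.asarray([lo, *np.asarray(internal_knots, float), hi])
    if np.any(np.diff(knots) <= 0):
        raise ValueError(f"knots must be strictly increasing, got {knots.tolist()}")
    K = len(knots)

    def d(k: int) -> np.ndarray:
        # ((x−κ_k)_+^3 − (x−κ_{K−1})_+^3) / (κ_{K−1} − κ_k)
        return (
            np.maximum(0.0, x - knots[k]) ** 3 - np.maximum(0.0, x - knots[K - 1]) ** 3
        ) / (knots[K - 1] - knots[k])

    cols = [x] + [d(k) - d(K - 2) for k in range(K - 2)]
    return np.column_stack(cols)


@dataclass(frozen=True)
class SplineBasis:
    """A resolved natural-spline basis: callable on temperatures."""

    internal_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.boundary_knots
        if not all(lo < k < hi for k in self.internal_knots):
            raise ValueError("boundary knots must bracket internal knots")

    def __call__(self, x) -> np.ndarray:
        return natural_spline_basis(x, self.internal_knots, self.boundary_knots)

    @property
    def ncol(self) -> int:
        return len(self.internal_knots) + 1


@dataclass(frozen=True)
class CrossBasisSpec:
    """Exposure-spline × unconstrained-lag tensor specification."""

    internal_knot_percentiles: tuple[float, ...] = (50.0, 90.0)
    max_lag: int = 3

    def __post_init__(self) -> None:
        p = self.internal_knot_percentiles
        if any(not (0.0 < q < 100.0) for q in p) or any(
            a >= b for a, b in zip(p, p[1:])
        ):
            raise ValueError("knot percentiles must be strictly increasing in (0, 100)")
        if self.max_lag < 0:
            raise ValueError("max_lag must be ≥ 0")

    def resolve(self, training_temps: np.ndarray) -> SplineBasis:
        """Place knots on the pooled training temperature distribution."""
        t = np.asarray(training_temps, float)
        internal = tuple(np.percentile(t, self.internal_knot_percentiles))
        return SplineBasis(internal_knots=internal, boundary_knots=(t.min(), t.max()))


def build_cross_basis(
    temps: pd.Series,
    basis: SplineBasis,
    max_lag: int,
    dates: pd.DatetimeIndex | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Row-per-day cross-basis matrix.

    Entry (t, j·(L+1)+ℓ) = b_j(x_{t−ℓ}).  Returns the matrix indexed by
    ``dates`` (default: the temperature index) and a boolean mask of rows
    with complete lag-0..L history; incomplete rows are NaN and flagged for
    exclusion by the caller.
    """
    temps = check_daily(temps, "temps")
    if dates is None:
        dates = temps.index
    ncb = basis.ncol
    out = np.full((len(dates), ncb * (max_lag + 1)), np.nan)
    valid = np.ones(len(dates), bool)
    for lag in range(max_lag + 1):
        lagged = temps.reindex(dates - pd.Timedelta(days=lag)).to_numpy()
        ok = np.isfinite(lagged)
        valid &= ok
        b = basis(np.where(ok, lagged, 0.0))
        for j in range(ncb):
            out[ok, j * (max_lag + 1) + lag] = b[ok, j]
    cols = [f"cb_s{j}_l{lag}" for j in range(ncb) for lag in range(max_lag + 1)]
    return pd.DataFrame(out, index=dates, columns=cols), valid


# ---------------------------------------------------------------------------
# confounder design
# ---------------------------------------------------------------------------

_DOW_NAMES = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


def build_covariates(dates: pd.DatetimeIndex, doy_spline_df: int = 4) -> pd.DataFrame:
    """Intercept, day-of-week, day-of-year spline, year, and interaction.

    Reference levels are Monday and the first year present.  The day-of-year
    natural spline has ``doy_spline_df`` columns (knots at the quantiles of
    the observed day-of-year range); the interaction crosses every spline
    column with every non-reference year indicator.
    """
    if doy_spline_df < 2:
        raise ValueError("doy_spline_df must be ≥ 2")
    n = len(dates)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}

    dow = dates.dayofweek.to_numpy()
    for d in range(1, 7):  # Monday is reference
        cols[f"dow_{_DOW_NAMES[d]}"] = (dow == d).astype(float)

    doy = dates.dayofyear.to_numpy(float)
    # df columns ⇒ df+1 knots: boundaries at min/max, internal at quantiles
    probs = np.linspace(0, 100, doy_spline_df + 1)[1:-1]
    internal = np.percentile(doy, probs)
    sb = natural_spline_basis(doy, internal, (doy.min(), doy.max()))
    for j in range(sb.shape[1]):
        cols[f"doy_s{j}"] = sb[:, j]

    years = dates.year.to_numpy()
    uniq = np.unique(years)
    for y in uniq[1:]:  # first year is reference
        cols[f"year_{y}"] = (years == y).astype(float)
        for j in range(sb.shape[1]):
            cols[f"doy_s{j}:year_{y}"] = sb[:, j] * (years == y)

    return pd.DataFrame(cols, index=dates)


# ---------------------------------------------------------------------------
# quasi-Poisson IRLS
# ---------------------------------------------------------------------------

@dataclass
class QuasiPoissonResult:
    coef: np.ndarray
    cov: np.ndarray          # dispersion-scaled
    dispersion: float
    fitted: np.ndarray
    deviance: float
    n_iter: int
    column_names: list[str] | None = None


class ConvergenceError(RuntimeError):
    pass


def _check_rank(X: np.ndarray, names) -> None:
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [names[i] if names else str(i) for i in piv[rank:]]
        raise np.linalg.LinAlgError(f"design is rank deficient; collinear columns: {bad}")


def fit_quasipoisson(
    y, X, tol: float = 1e-9, max_iter: int = 100
) -> QuasiPoissonResult:
    """Quasi-Poisson GLM with log link, via iteratively reweighted LS.

    Coefficients maximise the Poisson log-likelihood; the dispersion is the
    Pearson statistic over residual degrees of freedom and scales the
    covariance ``φ·(XᵀWX)⁻¹`` evaluated at convergence.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    _check_rank(X, names)

    beta = np.zeros(p)
    intercept_like = np.all(X[:, 0] == 1.0)
    if intercept_like:
        beta[0] = np.log(max(y.mean(), 1e-12))

    def deviance(mu: np.ndarray) -> float:
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        return 2.0 * float(np.sum(term - (y - mu)))

    trace = []
    converged = False
    eta = np.clip(X @ beta, -30.0, 30.0)
    for it in range(1, max_iter + 1):
        mu = np.exp(eta)
        w = mu
        z = eta + (y - mu) / mu
        xtw = X.T * w
        beta_new = linalg.solve(xtw @ X, xtw @ z, assume_a="pos")
        eta_new = np.clip(X @ beta_new, -30.0, 30.0)
        dev = deviance(np.exp(eta_new))
        trace.append(dev)
        step = np.max(np.abs(beta_new - beta)) / (1.0 + np.max(np.abs(beta_new)))
        beta, eta = beta_new, eta_new
        if step <= tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations; deviance trace tail "
            f"{[round(d, 6) for d in trace[-5:]]}"
        )

    mu = np.exp(eta)
    pearson = float(np.sum((y - mu) ** 2 / mu))
    dispersion = pearson / (n - p)
    xtwx = (X.T * mu) @ X
    cov = dispersion * linalg.inv(xtwx)
    cov = 0.5 * (cov + cov.T)
    return QuasiPoissonResult(
        coef=beta,
        cov=cov,
        dispersion=dispersion,
        fitted=mu,
        deviance=trace[-1],
        n_iter=it,
        column_names=names,
    )


# ---------------------------------------------------------------------------
# cumulative association, MMT, centring
# ---------------------------------------------------------------------------

def find_mmt(curve, lower: float, upper: float, grid_step: float = 0.1) -> float:
    """Argmin of a cumulative risk curve on a regular grid over [lower, upper].

    Ties break toward the lower temperature.  The lower bound is typically
    the 50th training percentile, the upper bound the training maximum.
    """
    if not (lower < upper):
        raise ValueError(f"degenerate MMT search interval [{lower}, {upper}]")
    grid = np.arange(lower, upper + grid_step / 2.0, grid_step)
    vals = np.asarray(curve(grid), float)
    return float(grid[int(np.argmin(vals))])


@dataclass
class FittedAssociation:
    """A fitted cumulative temperature–mortality association.

    Holds the full coefficient vector and dispersion-scaled covariance, the
    location of the cross-basis block, the resolved spline basis, the MMT,
    and the training temperature quantiles.  ``centered_curve`` evaluates
    the cumulative log-RR relative to the MMT.
    """

    coef: np.ndarray
    cov: np.ndarray
    dispersion: float
    column_names: list[str]
    crossbasis_index: np.ndarray
    basis: SplineBasis
    max_lag: int
    mmt: float
    training_percentiles: dict[float, float]
    mmt_grid_step: float = 0.1

    @property
    def crossbasis_coef(self) -> np.ndarray:
        return self.coef[self.crossbasis_index]

    @property
    def crossbasis_cov(self) -> np.ndarray:
        return self.cov[np.ix_(self.crossbasis_index, self.crossbasis_index)]

    def _lag_summed(self, cb_coef: np.ndarray | None = None) -> np.ndarray:
        cb = self.crossbasis_coef if cb_coef is None else np.asarray(cb_coef, float)
        return cb.reshape(self.basis.ncol, self.max_lag + 1).sum(axis=1)

    def cumulative_curve(self, x, cb_coef: np.ndarray | None = None) -> np.ndarray:
        """Uncentered cumulative log-RR: Σ_j (Σ_ℓ β_{jℓ}) · b_j(x)."""
        return self.basis(np.asarray(x, float)) @ self._lag_summed(cb_coef)

    def centered_curve(self, x, cb_coef: np.ndarray | None = None) -> np.ndarray:
        """Cumulative log-RR centred so the curve is zero at the MMT."""
        c = self._lag_summed(cb_coef)
        ref = self.basis(np.asarray([self.mmt])) @ c
        return self.basis(np.asarray(x, float)) @ c - ref[0]

    def curve_slope_above_mmt(self) -> float:
        """Least-squares slope of the centred curve on [MMT, training max].

        A scalar summary comparable with a known log-linear risk increase
        per °C above the optimum.
        """
        upper = self.training_percentiles[100.0]
        if upper <= self.mmt:
            return float("nan")
        grid = np.arange(self.mmt, upper + self.mmt_grid_step / 2, self.mmt_grid_step)
        vals = self.centered_curve(grid)
        d = grid - self.mmt
        denom = float(d @ d)
        return float(d @ vals / denom) if denom > 0 else float("nan")


class DLNMHeatModel(BaseEstimator):
    """Quasi-Poisson DLNM of daily deaths on daily mean temperature.

    Parameters
    ----------
    internal_knot_percentiles : tuple of float
        Exposure-spline knot placement on the pooled training temperatures.
    max_lag : int
        Deepest lag (days) of the unconstrained lag dimension.
    doy_spline_df : int
        Degrees of freedom of the day-of-year confounder spline.
    mmt_lower_percentile : float
        Lower bound of the MMT search, as a training-temperature percentile.
    mmt_grid_step : float
        Grid resolution (°C) of the MMT search.
    tol, max_iter :
        IRLS convergence settings.

    Attributes (after :meth:`fit`)
    ------------------------------
    coef_, cov_, dispersion_ : fitted GLM quantities
    mmt_ : float — minimum mortality temperature (°C)
    association_ : FittedAssociation
    n_obs_ : int — days entering the likelihood
    """

    def __init__(
        self,
        internal_knot_percentiles: tuple[float, ...] = (50.0, 90.0),
        max_lag: int = 3,
        doy_spline_df: int = 4,
        mmt_lower_percentile: float = 50.0,
        mmt_grid_step: float = 0.1,
        tol: float = 1e-9,
        max_iter: int = 100,
    ):
        self.internal_knot_percentiles = internal_knot_percentiles
        self.max_lag = max_lag
        self.doy_spline_df = doy_spline_df
        self.mmt_lower_percentile = mmt_lower_percentile
        self.mmt_grid_step = mmt_grid_step
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, temps: pd.Series, deaths: pd.Series) -> "DLNMHeatModel":
        """Fit on training summers.

        ``deaths`` indexes the modelled days; ``temps`` must additionally
        cover the ``max_lag`` days preceding each modelled day (lead-in
        days), otherwise days lacking full lag history are dropped from the
        likelihood.
        """
        temps = check_daily(temps, "temps")
        deaths = check_deaths(deaths, "deaths")

        spec = CrossBasisSpec(
            internal_knot_percentiles=tuple(self.internal_knot_percentiles),
            max_lag=self.max_lag,
        )
        train_temps = temps.reindex(deaths.index)
        if train_temps.isna().any():
            missing = deaths.index[train_temps.isna().to_numpy()][0]
            raise ValueError(f"temperature missing on modelled day {missing.date()}")
        basis = spec.resolve(train_temps.to_numpy())

        cb, valid = build_cross_basis(temps, basis, self.max_lag, dates=deaths.index)
        covars = build_covariates(deaths.index, self.doy_spline_df)
        design = pd.concat([covars, cb], axis=1).loc[valid]
        y = deaths.loc[valid]

        res = fit_quasipoisson(y, design, tol=self.tol, max_iter=self.max_iter)

        cb_index = np.array(
            [i for i, c in enumerate(design.columns) if c.startswith("cb_")]
        )
        pct_probs = sorted(
            {0.0, 100.0, self.mmt_lower_percentile, *map(float, self.internal_knot_percentiles)}
        )
        pct = {q: float(np.percentile(train_temps, q)) for q in pct_probs}

        assoc = FittedAssociation(
            coef=res.coef,
            cov=res.cov,
            dispersion=res.dispersion,
            column_names=list(design.columns),
            crossbasis_index=cb_index,
            basis=basis,
            max_lag=self.max_lag,
            mmt=float("nan"),
            training_percentiles=pct,
            mmt_grid_step=self.mmt_grid_step,
        )
        assoc.mmt = find_mmt(
            assoc.cumulative_curve,
            pct[self.mmt_lower_percentile],
            pct[100.0],
            self.mmt_grid_step,
        )

        self.association_ = assoc
        self.coef_ = res.coef
        self.cov_ = res.cov
        self.dispersion_ = res.dispersion
        self.mmt_ = assoc.mmt
        self.n_obs_ = len(y)
        self.n_iter_ = res.n_iter
        return self

    def cumulative_log_rr(self, x) -> np.ndarray:
        """Centred cumulative log relative risk at temperature(s) ``x``."""
        if not hasattr(self, "association_"):
            raise RuntimeError("fit() before cumulative_log_rr()")
        return self.association_.centered_curve(x)
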