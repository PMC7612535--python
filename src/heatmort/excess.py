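"""Excess-death estimation against within-summer baselines.

The surveillance-style estimator: expected deaths come either from a linear
trend fitted to all non-heatwave days of the baseline period, or (the
pandemic-season variant) from averaging a window of non-heatwave days on
either side of each heatwave.  Excess is the cumulative observed-minus-
expected difference over a heatwave, with a confidence interval scaled from
the day-to-day standard deviation of non-heatwave deaths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .heatwaves import HeatwavePeriod
from .series import check_deaths

__all__ = [
    "BaselineSpec",
    "MortalityEstimate",
    "expected_deaths",
    "nonheatwave_sd",
    "excess_deaths",
    "combine_estimates",
    "UKHSAExcess",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class BaselineSpec:
    """How expected (baseline) deaths are constructed.

    ``linear_trend`` regresses observed deaths on time over all non-heatwave
    days of the baseline period; ``window_mean`` averages the nearest
    ``window_half_width`` non-heatwave days strictly before and after each
    heatwave.
    """

    method: str = "linear_trend"
    baseline_start: pd.Timestamp | None = None
    baseline_end: pd.Timestamp | None = None
    window_half_width: int = 7

    def __post_init__(self) -> None:
        if self.method not in ("linear_trend", "window_mean"):
            raise ValueError(f"unknown baseline method {self.method!r}")
        if self.window_half_width < 1:
            raise ValueError("window_half_width must be ≥ 1")
        if (
            self.baseline_start is not None
            and self.baseline_end is not None
            and pd.Timestamp(self.baseline_start) > pd.Timestamp(self.baseline_end)
        ):
            raise ValueError("baseline_start after baseline_end")


@dataclass(frozen=True)
class MortalityEstimate:
    """Central estimate with a 95% interval, tagged by region/period/method."""

    central: float
    ci_low: float
    ci_high: float
    region: str = ""
    period: object = None
    method: str = "ukhsa"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.central <= self.ci_high):
            raise ValueError(
                f"interval out of order: [{self.ci_low}, {self.central}, {self.ci_high}]"
            )

    @property
    def halfwidth_upper(self) -> float:
        return self.ci_high - self.central

    @property
    def halfwidth_lower(self) -> float:
        return self.central - self.ci_low

    def contains(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def _heatwave_mask(index: pd.DatetimeIndex, heatwaves: Sequence[HeatwavePeriod]) -> np.ndarray:
    """True on days inside any heatwave's *extended* bounds."""
    mask = np.zeros(len(index), bool)
    for hw in heatwaves:
        mask |= (index >= hw.start) & (index <= hw.end)
    return mask


def _baseline_slice(observed: pd.Series, spec: BaselineSpec) -> pd.Series:
    start = spec.baseline_start if spec.baseline_start is not None else observed.index[0]
    end = spec.baseline_end if spec.baseline_end is not None else observed.index[-1]
    out = observed.loc[pd.Timestamp(start) : pd.Timestamp(end)]
    if out.empty:
        raise ValueError("baseline period contains no observed days")
    return out


def expected_deaths(
    observed: pd.Series,
    heatwaves: Sequence[HeatwavePeriod],
    spec: BaselineSpec,
) -> pd.Series:
    """Expected (baseline) deaths over the baseline period.

    ``linear_trend``: OLS of deaths on integer day index over non-heatwave
    baseline days, evaluated on every baseline day.  ``window_mean``: a
    per-heatwave constant — the mean of the nearest ``window_half_width``
    non-heatwave days strictly before and strictly after that heatwave;
    non-heatwave days are left NaN since this variant defines no baseline
    for them.
    """
    observed = check_deaths(observed, "observed")
    obs = _baseline_slice(observed, spec)
    hw_mask = _heatwave_mask(obs.index, heatwaves)

    if spec.method == "linear_trend":
        keep = ~hw_mask
        if keep.sum() < 3:
            raise ValueError("fewer than 3 non-heatwave baseline days for the trend fit")
        t = (obs.index - obs.index[0]).days.to_numpy(float)
        slope, intercept = np.polyfit(t[keep], obs.to_numpy(float)[keep], 1)
        return pd.Series(intercept + slope * t, index=obs.index, name="expected")

    # window_mean: constant per heatwave from flanking non-heatwave days
    expected = pd.Series(np.nan, index=obs.index, name="expected")
    nonhw_dates = obs.index[~hw_mask]
    values = obs[~hw_mask]
    w = spec.window_half_width
    for hw in heatwaves:
        if hw.end < obs.index[0] or hw.start > obs.index[-1]:
            continue
        before = values[nonhw_dates < hw.start]
        after = values[nonhw_dates > hw.end]
        if len(before) < w or len(after) < w:
            raise ValueError(
                f"window of {w} non-heatwave days not available around "
                f"{hw.start.date()}–{hw.end.date()}"
            )
        level = float(np.concatenate([before.iloc[-w:], after.iloc[:w]]).mean())
        in_hw = (obs.index >= hw.start) & (obs.index <= hw.end)
        expected[in_hw] = level
    return expected


def nonheatwave_sd(
    observed: pd.Series, heatwaves: Sequence[HeatwavePeriod], spec: BaselineSpec
) -> float:
    """Sample SD of deaths on non-heatwave days of the baseline period."""
    obs = _baseline_slice(check_deaths(observed, "observed"), spec)
    keep = ~_heatwave_mask(obs.index, heatwaves)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-heatwave days for the SD")
    return float(obs[keep].std(ddof=1))


def excess_deaths(
    observed: pd.Series,
    expected: pd.Series,
    period: HeatwavePeriod,
    nonheatwave_sd: float,
    *,
    region: str = "",
    z: float = Z95,
) -> MortalityEstimate:
    """Cumulative observed − expected over one heatwave period.

    The 95% interval halfwidth is ``z · s · sqrt(L)`` with ``s`` the
    non-heatwave daily SD and ``L`` the period length in days, treating the
    period sum as an L-fold accumulation of day-level noise.
    """
    days = period.days
    obs = observed.reindex(days)
    exp_ = expected.reindex(days)
    if obs.isna().any():
        raise ValueError(f"observed deaths missing inside {period.start.date()}–{period.end.date()}")
    if exp_.isna().any():
        raise ValueError(f"expected deaths missing inside {period.start.date()}–{period.end.date()}")
    central = float((obs - exp_).sum())
    hw = z * nonheatwave_sd * np.sqrt(len(days))
    return MortalityEstimate(
        central=central,
        ci_low=central - hw,
        ci_high=central + hw,
        region=region,
        period=period,
        method="ukhsa",
    )


def combine_estimates(parts: Sequence[MortalityEstimate]) -> MortalityEstimate:
    """Sum estimates; combine interval halfwidths in quadrature.

    The upper halfwidth of the total is the square root of the sum of squared
    upper halfwidths of the parts (lower analogous) — the aggregation used to
    pool per-stratum excess estimates into a total.
    """
    parts = list(parts)
    if not parts:
        raise ValueError("no estimates to combine")
    methods = {p.method for p in parts}
    if len(methods) > 1:
        raise ValueError(f"mixed method tags {sorted(methods)} cannot be combined")
    if len(parts) == 1:
        return parts[0]
    central = sum(p.central for p in parts)
    up = float(np.sqrt(sum(p.halfwidth_upper**2 for p in parts)))
    lo = float(np.sqrt(sum(p.halfwidth_lower**2 for p in parts)))
    regions = {p.region for p in parts}
    return MortalityEstimate(
        central=central,
        ci_low=central - lo,
        ci_high=central + up,
        region=regions.pop() if len(regions) == 1 else "combined",
        period="combined",
        method=methods.pop(),
    )


class UKHSAExcess(BaseEstimator):
    """Surveillance-style heatwave excess-death estimator.

    Parameters
    ----------
    method : {'linear_trend', 'window_mean'}
        Baseline construction (see :func:`expected_deaths`).
    window_half_width : int
        Days on each side for the ``window_mean`` baseline.
    z : float
        Normal quantile for the interval (1.96 for 95%).

    Attributes (after :meth:`fit`)
    ------------------------------
    expected_ : pandas.Series
        Baseline expected deaths over the baseline period.
    sd_ : float
        Day-to-day SD of non-heatwave deaths.
    heatwaves_ : list of HeatwavePeriod
    estimates_ : list of MortalityEstimate
        Per-heatwave excess estimates.
    """

    def __init__(self, method: str = "linear_trend", window_half_width: int = 7, z: float = Z95):
        self.method = method
        self.window_half_width = window_half_width
        self.z = z

    def fit(
        self,
        observed: pd.Series,
        heatwaves: Sequence[HeatwavePeriod],
        baseline: tuple | None = None,
        region: str = "",
    ) -> "UKHSAExcess":
        start, end = baseline if baseline is not None else (None, None)
        spec = BaselineSpec(
            method=self.method,
            baseline_start=start,
            baseline_end=end,
            window_half_width=self.window_half_width,
        )
        observed = check_deaths(observed, "observed")
        self.spec_ = spec
        self.region_ = region
        span_lo = pd.Timestamp(start) if start is not None else observed.index[0]
        span_hi = pd.Timestamp(end) if end is not None else observed.index[-1]
        # extension days beyond the baseline period carry no observations
        self.heatwaves_ = [hw.clip_to(span_lo, span_hi) for hw in heatwaves]
        self.expected_ = expected_deaths(observed, self.heatwaves_, spec)
        self.sd_ = nonheatwave_sd(observed, self.heatwaves_, spec)
        self.estimates_ = [
            excess_deaths(observed, self.expected_, hw, self.sd_, region=region, z=self.z)
            for hw in self.heatwaves_
        ]
        return self

    def total(self) -> MortalityEstimate:
        """Combined excess over all fitted heatwaves."""
        if not hasattr(self, "estimates_"):
            raise RuntimeError("fit() before total()")
        return combine_estimates(self.estimates_)
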