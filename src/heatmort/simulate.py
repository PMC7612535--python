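"""Synthetic regional daily temperature and mortality series.

The generator produces summer-block (1 May – 30 Sep) data with a known
temperature–mortality structure so every downstream stage — heatwave
detection, baseline excess estimation, distributed-lag model fitting and
attribution — can be tested against bookkept truth without any downloads.

The generative model mirrors the analysis model it is meant to exercise:

* temperature = seasonal sinusoid + AR(1) noise + injected heat episodes,
* deaths ~ overdispersed Poisson with log-mean
  ``log(baseline) + log(dow) + log(season) + log(year)
  + Σ_ℓ w_ℓ · β · max(0, x_{t−ℓ} − MMT)``,
  i.e. a hockey-stick cumulative association above a known optimum
  temperature distributed over lags 0..3,
* a Central-England-Temperature-like series as a weighted average of the
  regional series plus noise, with "alert days" marking injected episodes.

Each summer block carries ``lead_in_days`` extra temperature days before
1 May so that every in-block day has a full lag history.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .series import check_daily, summer_index

__all__ = [
    "HeatEpisode",
    "SimulationConfig",
    "TruthRecord",
    "SyntheticRegionData",
    "StudyData",
    "simulate_temperature",
    "simulate_deaths",
    "simulate_cet_and_alerts",
    "simulate_region",
    "simulate_study",
    "default_config",
    "null_config",
]


@dataclass(frozen=True)
class HeatEpisode:
    """A heat bump injected into the temperature series.

    ``start_offset`` is the day offset from 1 May (0-based); the bump adds
    ``bump_c`` °C on ``length`` consecutive days.  ``summers`` selects which
    summer blocks receive the episode (``None`` = every block).
    """

    start_offset: int
    length: int
    bump_c: float
    summers: tuple[int, ...] | None = None

    def applies_to(self, summer: int) -> bool:
        return self.summers is None or summer in self.summers


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults describe a plausible English region: ~120 all-cause deaths per
    day, summer mean temperatures ~13–18 °C with AR(1) day-to-day
    persistence, an optimum temperature of 17 °C (≈65th percentile of the
    simulated summer distribution) and a cumulative relative risk of
    1.05 per °C above it, spread over lags 0–3.
    """

    n_summers: int = 11
    region_names: tuple[str, ...] = ("North", "South")
    seed: int = 0
    start_year: int = 2001
    # temperature process
    temp_base: float = 12.5          # °C, annual mean level of the sinusoid
    temp_amplitude: float = 5.5      # °C, seasonal amplitude
    temp_peak_doy: int = 197         # day of year of the seasonal peak (mid July)
    temp_ar1: float = 0.65           # AR(1) coefficient, in [0, 1)
    temp_noise_sd: float = 1.6       # °C, innovation SD
    episode_spec: tuple[HeatEpisode, ...] = (
        HeatEpisode(70, 5, 4.0),     # mid-July episode
        HeatEpisode(100, 3, 3.0),    # early-August episode
    )
    # mortality process
    baseline_rate: float = 120.0     # expected deaths/day before modifiers
    dow_effects: tuple[float, ...] = (1.02, 1.0, 1.0, 1.0, 1.0, 0.97, 0.96)
    season_effect_amplitude: float = 0.06   # log-scale annual cosine amplitude
    year_effects: tuple[float, ...] | None = None   # per-summer multipliers
    true_mmt: float = 17.0           # °C, optimum temperature
    true_log_rr_per_degc: float = float(np.log(1.05))  # cumulative log-RR/°C
    lag_weights: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)
    overdispersion: float = 1.3      # variance/mean inflation, ≥ 1
    # CET construction
    cet_weights: tuple[float, ...] | None = None    # per-region, default equal
    cet_noise_sd: float = 0.3        # °C
    lead_in_days: int = 3

    def __post_init__(self) -> None:
        if self.n_summers < 1:
            raise ValueError("n_summers must be ≥ 1")
        if not (0.0 <= self.temp_ar1 < 1.0):
            raise ValueError(f"temp_ar1 must be in [0, 1), got {self.temp_ar1}")
        if self.temp_noise_sd < 0:
            raise ValueError("temp_noise_sd must be ≥ 0")
        if self.overdispersion < 1.0:
            raise ValueError("overdispersion must be ≥ 1")
        if len(self.dow_effects) != 7:
            raise ValueError("dow_effects must have 7 entries (Mon..Sun)")
        w = np.asarray(self.lag_weights, float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("lag_weights must be non-negative and sum to 1")
        if self.year_effects is not None and len(self.year_effects) != self.n_summers:
            raise ValueError("year_effects must have one entry per summer")
        if self.cet_weights is not None and len(self.cet_weights) != len(self.region_names):
            raise ValueError("cet_weights must have one entry per region")
        if self.lead_in_days < len(self.lag_weights) - 1:
            raise ValueError("lead_in_days must cover the lag depth")

    @property
    def years(self) -> range:
        return range(self.start_year, self.start_year + self.n_summers)


@dataclass
class TruthRecord:
    """Generator-side bookkeeping used to score downstream estimates."""

    true_mmt: float
    true_log_rr_per_degc: float
    lag_weights: tuple[float, ...]
    #: expected deaths per day, E[count]
    mu: pd.Series
    #: expected attributable deaths per day, mu·(1 − exp(−c_t))
    attributable: pd.Series

    def true_curve(self, x) -> np.ndarray:
        """Cumulative log-RR curve: hockey stick above the optimum."""
        x = np.asarray(x, float)
        return self.true_log_rr_per_degc * np.maximum(0.0, x - self.true_mmt)

    def attributable_total(self, start=None, end=None) -> float:
        s = self.attributable
        if start is not None or end is not None:
            s = s.loc[start:end]
        return float(s.sum())


@dataclass
class SyntheticRegionData:
    region: str
    temperatures: pd.Series   # includes lead-in days per block
    deaths: pd.Series         # in-block days only
    truth: TruthRecord


@dataclass
class StudyData:
    """One synthetic multi-region study: regional data + shared CET/alerts."""

    config: SimulationConfig
    regions: dict[str, SyntheticRegionData]
    cet: pd.Series
    alert_days: frozenset


def _rng(config: SimulationConfig, region: str, stream: str) -> np.random.Generator:
    """Deterministic per-(seed, region, stream) generator."""
    key = [int(config.seed), zlib.crc32(region.encode()), zlib.crc32(stream.encode())]
    return np.random.default_rng(np.random.SeedSequence(key))


def _seasonal_mean(config: SimulationConfig, dates: pd.DatetimeIndex) -> np.ndarray:
    doy = dates.dayofyear.to_numpy(float)
    return config.temp_base + config.temp_amplitude * np.cos(
        2.0 * np.pi * (doy - config.temp_peak_doy) / 365.25
    )


def _episode_bump(config: SimulationConfig, summer: int, n_days: int) -> np.ndarray:
    """Additive °C per day of one lead-in-padded summer block."""
    bump = np.zeros(n_days)
    lead = config.lead_in_days
    for ep in config.episode_spec:
        if not ep.applies_to(summer):
            continue
        lo = lead + ep.start_offset
        hi = min(lo + ep.length, n_days)
        if lo < 0 or lo >= n_days:
            raise ValueError(f"episode offset {ep.start_offset} outside summer block")
        bump[lo:hi] += ep.bump_c
    return bump


def simulate_temperature(config: SimulationConfig, region: str) -> pd.Series:
    """Simulate daily mean temperature for one region, all summer blocks.

    Seasonal sinusoid + stationary AR(1) noise + configured heat episodes.
    Includes ``lead_in_days`` days before each 1 May.  Deterministic given
    the config (incl. seed).
    """
    rng = _rng(config, region, "temp")
    pieces = []
    for s, year in enumerate(config.years):
        idx = summer_index(year, config.lead_in_days)
        n = len(idx)
        mean = _seasonal_mean(config, idx)
        noise = np.zeros(n)
        if config.temp_noise_sd > 0:
            stat_sd = config.temp_noise_sd / np.sqrt(1.0 - config.temp_ar1**2)
            noise[0] = rng.normal(0.0, stat_sd)
            innov = rng.normal(0.0, config.temp_noise_sd, n - 1)
            for t in range(1, n):
                noise[t] = config.temp_ar1 * noise[t - 1] + innov[t - 1]
        pieces.append(pd.Series(mean + noise + _episode_bump(config, s, n), index=idx))
    out = pd.concat(pieces)
    out.name = region
    return out


def _heat_log_rr(config: SimulationConfig, temps: pd.Series, dates: pd.DatetimeIndex) -> np.ndarray:
    """Per-day cumulative heat log-RR, Σ_ℓ w_ℓ·β·max(0, x_{t−ℓ} − MMT)."""
    w = np.asarray(config.lag_weights, float)
    beta = config.true_log_rr_per_degc
    exceed = np.maximum(0.0, temps - config.true_mmt)
    c = np.zeros(len(dates))
    for lag, wl in enumerate(w):
        lagged = exceed.reindex(dates - pd.Timedelta(days=lag))
        if lagged.isna().any():
            missing = dates[lagged.isna().to_numpy()][0]
            raise ValueError(f"temperature missing at lag {lag} for {missing.date()}")
        c += wl * beta * lagged.to_numpy()
    return c


def simulate_deaths(
    config: SimulationConfig, temps: pd.Series, region: str = ""
) -> tuple[pd.Series, TruthRecord]:
    """Simulate daily death counts given a temperature series.

    The mean is multiplicative in baseline rate, day-of-week, a winter-peaking
    seasonal cosine, a per-summer year effect, and the lag-distributed heat
    term; counts are gamma-mixed Poisson with variance = overdispersion·mean.
    """
    temps = check_daily(temps, "temps")
    rng = _rng(config, region, "deaths")
    year_eff = (
        np.ones(config.n_summers)
        if config.year_effects is None
        else np.asarray(config.year_effects, float)
    )
    dow = np.asarray(config.dow_effects, float)

    all_counts, all_mu, all_attr = [], [], []
    for s, year in enumerate(config.years):
        idx = summer_index(year)  # in-block days only
        c = _heat_log_rr(config, temps, idx)
        doy = idx.dayofyear.to_numpy(float)
        season = np.exp(
            config.season_effect_amplitude * np.cos(2.0 * np.pi * doy / 365.25)
        )
        mu = (
            config.baseline_rate
            * dow[idx.dayofweek.to_numpy()]
            * season
            * year_eff[s]
            * np.exp(c)
        )
        if not np.all(np.isfinite(mu)):
            bad = idx[~np.isfinite(mu)][0]
            raise FloatingPointError(f"non-finite death mean on {bad.date()}")
        phi = config.overdispersion
        if phi > 1.0:
            # gamma mixing with mean mu, var mu(phi−1) ⇒ count var = phi·mu
            lam = rng.gamma(shape=mu / (phi - 1.0), scale=phi - 1.0)
        else:
            lam = mu
        counts = rng.poisson(lam)
        all_counts.append(pd.Series(counts, index=idx))
        all_mu.append(pd.Series(mu, index=idx))
        all_attr.append(pd.Series(mu * (1.0 - np.exp(-c)), index=idx))

    deaths = pd.concat(all_counts)
    deaths.name = region or None
    truth = TruthRecord(
        true_mmt=config.true_mmt,
        true_log_rr_per_degc=config.true_log_rr_per_degc,
        lag_weights=tuple(config.lag_weights),
        mu=pd.concat(all_mu),
        attributable=pd.concat(all_attr),
    )
    return deaths, truth


def simulate_cet_and_alerts(
    config: SimulationConfig, regional_temps: dict[str, pd.Series]
) -> tuple[pd.Series, frozenset]:
    """Shared CET-like series (weighted regional average + noise) and the
    set of alert days (days inside configured episodes)."""
    if not regional_temps:
        raise ValueError("no regional temperature series supplied")
    names = list(regional_temps)
    weights = (
        np.full(len(names), 1.0 / len(names))
        if config.cet_weights is None
        else np.asarray(config.cet_weights, float) / np.sum(config.cet_weights)
    )
    stacked = pd.concat([regional_temps[n] for n in names], axis=1)
    cet = pd.Series(stacked.to_numpy() @ weights, index=stacked.index, name="CET")
    if config.cet_noise_sd > 0:
        rng = _rng(config, "__cet__", "cet")
        cet = cet + rng.normal(0.0, config.cet_noise_sd, len(cet))

    alerts = set()
    for s, year in enumerate(config.years):
        start = summer_index(year)[0]
        for ep in config.episode_spec:
            if ep.applies_to(s):
                for d in range(ep.length):
                    alerts.add(start + pd.Timedelta(days=ep.start_offset + d))
    return cet, frozenset(alerts)


def simulate_region(config: SimulationConfig, region: str) -> SyntheticRegionData:
    temps = simulate_temperature(config, region)
    deaths, truth = simulate_deaths(config, temps, region)
    return SyntheticRegionData(region=region, temperatures=temps, deaths=deaths, truth=truth)


def simulate_study(config: SimulationConfig) -> StudyData:
    """Simulate every configured region plus the shared CET/alert record."""
    regions = {name: simulate_region(config, name) for name in config.region_names}
    cet, alerts = simulate_cet_and_alerts(
        config, {n: d.temperatures for n, d in regions.items()}
    )
    return StudyData(config=config, regions=regions, cet=cet, alert_days=alerts)


def default_config(**overrides) -> SimulationConfig:
    """The standard study conditions."""
    return replace(SimulationConfig(), **overrides) if overrides else SimulationConfig()


def null_config(**overrides) -> SimulationConfig:
    """Zero heat effect and flat day-of-week/season/year modifiers.

    Used for null-calibration checks: any systematic excess or attributable
    signal found on these data is estimator bias.
    """
    base = SimulationConfig(
        true_log_rr_per_degc=0.0,
        dow_effects=(1.0,) * 7,
        season_effect_amplitude=0.0,
        year_effects=None,
    )
    return replace(base, **overrides) if overrides else base
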