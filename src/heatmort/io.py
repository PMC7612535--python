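"""Readers, writers, configuration and the end-to-end pipeline driver.

File conventions: tidy CSV with columns ``date`` (ISO-8601), ``region``,
``value`` for daily series; a one-column CSV of dates for alert days; a
start/end/raw/source CSV for heatwave periods; a documented JSON file for
persisted associations.  Dates are ISO-8601 throughout; intervals are
closed on both ends; temperatures are °C at 0.1 °C precision.
"""

from __future__ import annotations

import calendar
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .attribution import monte_carlo_ci
from .comparison import ComparisonRow, annual_totals
from .dlnm import DLNMHeatModel, FittedAssociation, SplineBasis
from .excess import MortalityEstimate, UKHSAExcess
from .heatwaves import HeatwaveCriteria, HeatwavePeriod, identify_heatwaves, load_configured_heatwaves
from .series import check_daily, check_deaths, summer_span

__all__ = [
    "read_daily_csv",
    "write_daily_csv",
    "read_alert_days",
    "write_alert_days",
    "read_hadcet_wide",
    "read_heatwaves_csv",
    "write_heatwaves_csv",
    "save_association",
    "load_association",
    "write_estimates_csv",
    "PipelineConfig",
    "run_pipeline",
]

logger = logging.getLogger("heatmort")

HADCET_SENTINEL = -999


# ---------------------------------------------------------------------------
# tidy daily CSV
# ---------------------------------------------------------------------------

def read_daily_csv(path, value_kind: str = "temperature", region: str | None = None):
    """Read a tidy daily CSV (columns date, region, value).

    Returns a dict ``{region: Series}`` or a single Series when ``region``
    is given.  Deaths are validated as non-negative integers.  Errors name
    the offending line (1-based, counting the header).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"region": str})
    required = {"date", "region", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path.name}: expected columns {sorted(required)}, got {list(df.columns)}")
    dates = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    if dates.isna().any():
        line = int(dates.index[dates.isna()][0]) + 2
        raise ValueError(f"{path.name}:{line}: unparseable date {df['date'][line - 2]!r}")
    df = df.assign(date=dates)
    dup = df.duplicated(subset=["date", "region"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise ValueError(f"{path.name}:{line}: duplicate (date, region) row")
    out: dict[str, pd.Series] = {}
    for name, grp in df.groupby("region", sort=True):
        s = pd.Series(grp["value"].to_numpy(), index=pd.DatetimeIndex(grp["date"]), name=name)
        s = s.sort_index()
        s.index.name = None
        if value_kind == "deaths":
            bad = (s.to_numpy() < 0) | (s.to_numpy() != np.round(s.to_numpy()))
            if bad.any():
                row = grp.index[np.argsort(grp["date"].to_numpy())][bad][0]
                raise ValueError(
                    f"{path.name}:{int(row) + 2}: invalid death count {s.to_numpy()[bad][0]}"
                )
            out[name] = check_deaths(s, f"deaths[{name}]")
        else:
            out[name] = check_daily(s, f"{value_kind}[{name}]")
    if region is not None:
        if region not in out:
            raise KeyError(f"{path.name}: region {region!r} not present (have {sorted(out)})")
        return out[region]
    return out


def write_daily_csv(series_by_region: dict[str, pd.Series], path) -> None:
    frames = [
        pd.DataFrame(
            {"date": s.index.strftime("%Y-%m-%d"), "region": name, "value": s.to_numpy()}
        )
        for name, s in sorted(series_by_region.items())
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_alert_days(path) -> frozenset:
    df = pd.read_csv(path)
    col = df.columns[0]
    return frozenset(pd.to_datetime(df[col], format="ISO8601"))


def write_alert_days(days, path) -> None:
    pd.DataFrame({"date": sorted(pd.Timestamp(d).strftime("%Y-%m-%d") for d in days)}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# HadCET wide layout
# ---------------------------------------------------------------------------

def read_hadcet_wide(path) -> pd.Series:
    """Parse the wide daily CET layout: ``year day m1 .. m12`` per line.

    Values are tenths of °C; the sentinel (−999) marks missing or
    non-existent calendar days.  Returns a tidy daily series in °C.
    """
    records: dict[pd.Timestamp, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 14:
                raise ValueError(
                    f"{Path(path).name}:{lineno}: expected 14 fields (year day m1..m12), "
                    f"got {len(parts)}"
                )
            try:
                year, day = int(parts[0]), int(parts[1])
                values = [int(v) for v in parts[2:]]
            except ValueError as exc:
                raise ValueError(f"{Path(path).name}:{lineno}: non-integer field") from exc
            for month, v in enumerate(values, start=1):
                if v == HADCET_SENTINEL:
                    continue
                if day > calendar.monthrange(year, month)[1]:
                    raise ValueError(
                        f"{Path(path).name}:{lineno}: value on impossible date "
                        f"{year}-{month:02d}-{day:02d}"
                    )
                records[pd.Timestamp(year, month, day)] = v / 10.0
    if not records:
        raise ValueError(f"{Path(path).name}: no data rows")
    s = pd.Series(records, name="CET").sort_index()
    return s


# ---------------------------------------------------------------------------
# heatwave CSV
# ---------------------------------------------------------------------------

def write_heatwaves_csv(periods: Sequence[HeatwavePeriod], path) -> None:
    pd.DataFrame(
        {
            "start": [p.start.strftime("%Y-%m-%d") for p in periods],
            "end": [p.end.strftime("%Y-%m-%d") for p in periods],
            "raw_start": [p.raw_start.strftime("%Y-%m-%d") for p in periods],
            "raw_end": [p.raw_end.strftime("%Y-%m-%d") for p in periods],
            "source": [p.source for p in periods],
        }
    ).to_csv(path, index=False)


def read_heatwaves_csv(path) -> list[HeatwavePeriod]:
    df = pd.read_csv(path)
    return [
        HeatwavePeriod(
            start=pd.Timestamp(r.start),
            end=pd.Timestamp(r.end),
            raw_start=pd.Timestamp(getattr(r, "raw_start", r.start)),
            raw_end=pd.Timestamp(getattr(r, "raw_end", r.end)),
            source=getattr(r, "source", "configured"),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# association persistence
# ---------------------------------------------------------------------------

def save_association(assoc: FittedAssociation, path) -> None:
    """Persist a fitted association as documented JSON."""
    payload = {
        "format": "heatmort-association",
        "version": 1,
        "coef": assoc.coef.tolist(),
        "cov": assoc.cov.tolist(),
        "dispersion": assoc.dispersion,
        "column_names": assoc.column_names,
        "crossbasis_index": assoc.crossbasis_index.tolist(),
        "internal_knots": list(assoc.basis.internal_knots),
        "boundary_knots": list(assoc.basis.boundary_knots),
        "max_lag": assoc.max_lag,
        "mmt": assoc.mmt,
        "training_percentiles": {str(k): v for k, v in assoc.training_percentiles.items()},
        "mmt_grid_step": assoc.mmt_grid_step,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_association(path) -> FittedAssociation:
    d = json.loads(Path(path).read_text())
    if d.get("format") != "heatmort-association":
        raise ValueError(f"{path}: not a heatmort association file")
    return FittedAssociation(
        coef=np.asarray(d["coef"]),
        cov=np.asarray(d["cov"]),
        dispersion=d["dispersion"],
        column_names=list(d["column_names"]),
        crossbasis_index=np.asarray(d["crossbasis_index"], int),
        basis=SplineBasis(
            internal_knots=tuple(d["internal_knots"]),
            boundary_knots=tuple(d["boundary_knots"]),
        ),
        max_lag=int(d["max_lag"]),
        mmt=float(d["mmt"]),
        training_percentiles={float(k): v for k, v in d["training_percentiles"].items()},
        mmt_grid_step=float(d["mmt_grid_step"]),
    )


def write_estimates_csv(estimates: Sequence[MortalityEstimate], path) -> None:
    records = []
    for e in estimates:
        period = e.period
        start = getattr(period, "start", None)
        end = getattr(period, "end", None)
        records.append(
            {
                "region": e.region,
                "period_start": start.strftime("%Y-%m-%d") if start is not None else str(period),
                "period_end": end.strftime("%Y-%m-%d") if end is not None else str(period),
                "central": e.central,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "method": e.method,
            }
        )
    pd.DataFrame.from_records(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything needed to drive one comparison run.

    ``target_years`` maps each analysed year to its settings: the training
    window (first, last training year), the baseline period, and optionally
    a verbatim list of heatwave periods (otherwise periods are detected
    from the CET series and alert days).
    """

    regions: list[str]
    deaths_csv: str
    temps_csv: str
    cet_csv: str | None = None
    alerts_csv: str | None = None
    target_years: dict[int, dict] = field(default_factory=dict)
    heatwave_source: str = "detect"          # detect | configured
    cet_threshold: float = 20.0
    extension_days: int = 1
    baseline_method: str = "linear_trend"    # linear_trend | window_mean
    n_mc: int = 100
    seed: int = 0
    use_raw_bounds: bool = False             # sum excess over raw, not extended, bounds

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def to_canonical(self) -> str:
        d = dict(self.__dict__)
        return json.dumps(d, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_canonical().encode()).hexdigest()[:16]

    def validate(self) -> None:
        if not self.regions:
            raise ValueError("config: no regions")
        if not self.target_years:
            raise ValueError("config: no target years")
        for year, cfg in self.target_years.items():
            if "train" not in cfg:
                raise ValueError(f"config: target year {year} lacks a training window")
        if self.heatwave_source not in ("detect", "configured"):
            raise ValueError(f"config: unknown heatwave_source {self.heatwave_source!r}")
        if self.heatwave_source == "detect" and self.cet_csv is None:
            raise ValueError("config: heatwave detection requires a CET series")


@dataclass
class PipelineResult:
    rows: list[ComparisonRow]
    annual: dict[int, tuple[MortalityEstimate, MortalityEstimate]]
    heatwaves: dict[int, list[HeatwavePeriod]]
    manifest: dict


def _stage(name: str, year: int | None = None, region: str | None = None):
    ctx = ", ".join(str(v) for v in (region, year) if v is not None)
    logger.info("stage %-12s %s", name, ctx)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Fit, attribute, estimate excess and compare, per region and year.

    For every region and target year: a distributed-lag model is fitted on
    the training-window summers, attribution runs over the target baseline
    period, the surveillance excess estimator runs on the same observed
    deaths and heatwaves, and one comparison row per region × heatwave is
    emitted, with national annual totals and a reproducibility manifest.
    """
    config.validate()
    for name, p in (("deaths", config.deaths_csv), ("temps", config.temps_csv),
                    ("cet", config.cet_csv), ("alerts", config.alerts_csv)):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"pipeline input {name!r} missing: {p}")

    _stage("read")
    deaths = read_daily_csv(config.deaths_csv, "deaths")
    temps = read_daily_csv(config.temps_csv, "temperature")
    missing = [r for r in config.regions if r not in deaths or r not in temps]
    if missing:
        raise ValueError(f"regions missing from inputs: {missing}")
    cet = read_daily_csv(config.cet_csv, "temperature", region="CET") if config.cet_csv else None
    alerts = read_alert_days(config.alerts_csv) if config.alerts_csv else frozenset()

    rows: list[ComparisonRow] = []
    annual: dict[int, tuple[MortalityEstimate, MortalityEstimate]] = {}
    heatwaves_by_year: dict[int, list[HeatwavePeriod]] = {}

    for year in sorted(config.target_years):
        ycfg = config.target_years[year]
        b_start, b_end = ycfg.get("baseline", summer_span(year))
        b_start, b_end = pd.Timestamp(b_start), pd.Timestamp(b_end)

        _stage("heatwaves", year)
        if config.heatwave_source == "configured" or "heatwaves" in ycfg:
            periods = load_configured_heatwaves(ycfg["heatwaves"])
        else:
            criteria = HeatwaveCriteria(
                cet_threshold=config.cet_threshold,
                extension_days=config.extension_days,
                alert_days=frozenset(d for d in alerts if b_start <= d <= b_end),
            )
            periods = [
                p.clip_to(b_start, b_end)
                for p in identify_heatwaves(cet.loc[b_start:b_end], criteria)
            ]
        heatwaves_by_year[year] = periods
        if not periods:
            logger.warning("no heatwaves in %s; skipping year", year)
            continue
        if config.use_raw_bounds:
            sum_periods = [
                HeatwavePeriod(p.raw_start, p.raw_end, p.raw_start, p.raw_end, p.source)
                for p in periods
            ]
        else:
            sum_periods = periods

        year_rows: list[ComparisonRow] = []
        draw_cols = []
        for region in config.regions:
            t0, t1 = ycfg["train"]
            train_start = pd.Timestamp(int(t0), 1, 1)
            train_end = pd.Timestamp(int(t1), 12, 31)

            _stage("fit", year, region)
            train_deaths = deaths[region].loc[train_start:train_end]
            if train_deaths.empty:
                raise ValueError(f"no training deaths for {region} in {t0}–{t1}")
            model = DLNMHeatModel().fit(temps[region], train_deaths)

            _stage("attribute", year, region)
            target_deaths = deaths[region].loc[b_start:b_end]
            seed = (config.seed * 100003 + zlib_crc(region) + year) % (2**31)
            dlnm_estimates, draws = monte_carlo_ci(
                model.association_,
                temps[region],
                target_deaths,
                sum_periods,
                n_mc=config.n_mc,
                seed=seed,
                region=region,
                return_draws=True,
            )

            _stage("excess", year, region)
            ukhsa = UKHSAExcess(method=config.baseline_method).fit(
                target_deaths, periods, baseline=(b_start, b_end), region=region
            )
            if config.use_raw_bounds:
                # baseline exclusion keeps the extended bounds; only the
                # summation window narrows to the raw run
                from .excess import excess_deaths as _excess

                ukhsa_estimates = [
                    _excess(target_deaths, ukhsa.expected_, p, ukhsa.sd_, region=region)
                    for p in sum_periods
                ]
            else:
                ukhsa_estimates = ukhsa.estimates_
            for hw, ue, de, k in zip(
                periods, ukhsa_estimates, dlnm_estimates, range(len(periods))
            ):
                year_rows.append(ComparisonRow(region=region, period=hw, ukhsa=ue, dlnm=de))
                draw_cols.append(draws[:, k])

        rows.extend(year_rows)
        _stage("totals", year)
        annual[year] = annual_totals(
            year_rows, dlnm_draw_totals=np.column_stack(draw_cols) if draw_cols else None
        )

    import heatmort

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_mc": config.n_mc,
        "package_version": getattr(heatmort, "__version__", "unknown"),
        "regions": config.regions,
        "years": sorted(config.target_years),
    }
    return PipelineResult(rows=rows, annual=annual, heatwaves=heatwaves_by_year, manifest=manifest)


def zlib_crc(text: str) -> int:
    import zlib

    return zlib.crc32(text.encode())
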