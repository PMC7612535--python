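"""UKHSA-style heatwave period identification.

A day qualifies if a Level-3 heat-health alert was in force *or* the mean
Central England Temperature exceeds a threshold (20 °C by default).  Maximal
runs of consecutive qualifying days form raw periods, each then extended by
one day on either side.  Officially published periods can instead be loaded
verbatim from configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import check_daily

__all__ = ["HeatwaveCriteria", "HeatwavePeriod", "identify_heatwaves", "load_configured_heatwaves"]

_DAY = pd.Timedelta(days=1)


@dataclass(frozen=True)
class HeatwaveCriteria:
    """Qualification rules: CET threshold (°C), symmetric extension (days),
    and the set of alert days."""

    cet_threshold: float = 20.0
    extension_days: int = 1
    alert_days: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not np.isfinite(self.cet_threshold):
            raise ValueError("cet_threshold must be finite")
        if self.extension_days < 0:
            raise ValueError("extension_days must be ≥ 0")


@dataclass(frozen=True, order=True)
class HeatwavePeriod:
    """Closed date interval with provenance.

    ``raw_start``/``raw_end`` bound the qualifying-day run before the ±1-day
    extension; ``start``/``end`` are the extended (possibly overlap-clipped)
    bounds actually used downstream.
    """

    start: pd.Timestamp
    end: pd.Timestamp
    raw_start: pd.Timestamp
    raw_end: pd.Timestamp
    source: str = "configured"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"period start {self.start.date()} after end {self.end.date()}")
        if not (self.start <= self.raw_start <= self.raw_end <= self.end):
            raise ValueError("raw interval must lie inside the extended interval")

    @property
    def days(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq="D")

    @property
    def length(self) -> int:
        return int((self.end - self.start).days) + 1

    def __contains__(self, date) -> bool:
        return self.start <= pd.Timestamp(date) <= self.end

    def clip_to(self, lo, hi) -> "HeatwavePeriod":
        """Intersect with a closed [lo, hi] span (e.g. the baseline period).

        Extension days falling outside the analysed span are dropped; the
        raw run is clipped likewise.  Raises if the intersection is empty.
        """
        lo, hi = pd.Timestamp(lo), pd.Timestamp(hi)
        start, end = max(self.start, lo), min(self.end, hi)
        if start > end:
            raise ValueError(
                f"period {self.start.date()}–{self.end.date()} lies outside "
                f"{lo.date()}–{hi.date()}"
            )
        raw_start = min(max(self.raw_start, start), end)
        raw_end = max(min(self.raw_end, end), start)
        return HeatwavePeriod(
            start=start, end=end, raw_start=raw_start, raw_end=raw_end, source=self.source
        )


def identify_heatwaves(cet: pd.Series, criteria: HeatwaveCriteria) -> list[HeatwavePeriod]:
    """Detect heatwave periods from a daily CET series plus alert days.

    Qualifying days are alert days or days with CET strictly above the
    threshold; maximal runs of consecutive qualifying days become raw
    periods, each extended by ``extension_days`` on both sides.  When the
    extended interval of a period would reach into the previous period's
    extended interval, its start is clipped to the day after — adjacent
    heatwaves separated by a single cool day stay distinct and no day is
    counted twice.  Alert days outside the CET span are ignored.
    """
    cet = check_daily(cet, "cet", contiguous=True)
    dates = cet.index
    qualifies = cet.to_numpy() > criteria.cet_threshold
    alert_mask = np.zeros(len(dates), bool)
    if criteria.alert_days:
        alert_mask = dates.isin(pd.DatetimeIndex(sorted(criteria.alert_days)))
    qual = qualifies | alert_mask

    periods: list[HeatwavePeriod] = []
    i, n = 0, len(dates)
    while i < n:
        if not qual[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and qual[j + 1]:
            j += 1
        raw_start, raw_end = dates[i], dates[j]
        had_cet = bool(qualifies[i : j + 1].any())
        had_alert = bool(alert_mask[i : j + 1].any())
        source = "both" if (had_cet and had_alert) else ("cet" if had_cet else "alert")
        ext = pd.Timedelta(days=criteria.extension_days)
        start, end = raw_start - ext, raw_end + ext
        if periods and start <= periods[-1].end:
            start = periods[-1].end + _DAY
        periods.append(
            HeatwavePeriod(start=start, end=end, raw_start=raw_start, raw_end=raw_end, source=source)
        )
        i = j + 1
    return periods


def load_configured_heatwaves(intervals) -> list[HeatwavePeriod]:
    """Build verbatim periods from (start, end) pairs or mappings.

    Used when officially published heatwave periods override detection.
    Periods are returned sorted; overlapping intervals are rejected.
    """
    periods = []
    for item in intervals:
        if isinstance(item, dict):
            start, end = item["start"], item["end"]
        else:
            start, end = item
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        periods.append(
            HeatwavePeriod(start=start, end=end, raw_start=start, raw_end=end, source="configured")
        )
    periods.sort()
    for prev, cur in zip(periods, periods[1:]):
        if cur.start <= prev.end:
            raise ValueError(
                f"configured heatwaves overlap: {prev.start.date()}–{prev.end.date()} "
                f"and {cur.start.date()}–{cur.end.date()}"
            )
    return periods
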