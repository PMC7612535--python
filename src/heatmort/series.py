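"""Shared daily-series conventions and validation.

Every stage of the package works on plain :class:`pandas.Series` objects with
a daily :class:`~pandas.DatetimeIndex`; deaths are non-negative integers,
temperatures are °C.  The summer convention (1 May – 30 September, 153 days)
is defined here once and imported everywhere else.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: First calendar day of the summer analysis block (month, day).
SUMMER_START = (5, 1)
#: Last calendar day of the summer analysis block (month, day).
SUMMER_END = (9, 30)
#: Number of days in a summer block.
SUMMER_LENGTH = 153


def summer_span(year: int) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Closed (start, end) timestamps of the summer block of ``year``."""
    return (
        pd.Timestamp(year, *SUMMER_START),
        pd.Timestamp(year, *SUMMER_END),
    )


def summer_index(year: int, lead_in_days: int = 0) -> pd.DatetimeIndex:
    """Daily index for one summer block, optionally with leading days.

    ``lead_in_days`` extra days before 1 May give each in-block day a full
    lag history without fabricating exposures.
    """
    start, end = summer_span(year)
    return pd.date_range(start - pd.Timedelta(days=lead_in_days), end, freq="D")


def check_daily(series: pd.Series, name: str = "series", *, contiguous: bool = False) -> pd.Series:
    """Validate a date-indexed daily numeric series; return it sorted.

    Raises ``ValueError`` on empty input, a non-datetime index, duplicate
    dates, or (when ``contiguous=True``) missing days inside the span.
    """
    if series.empty:
        raise ValueError(f"{name}: empty series")
    if not isinstance(series.index, pd.DatetimeIndex):
        raise ValueError(f"{name}: index must be a DatetimeIndex")
    if series.index.has_duplicates:
        dups = series.index[series.index.duplicated()].unique()
        raise ValueError(f"{name}: duplicate dates {list(dups[:5])}")
    out = series.sort_index()
    if contiguous:
        full = pd.date_range(out.index[0], out.index[-1], freq="D")
        if len(full) != len(out):
            missing = full.difference(out.index)
            raise ValueError(
                f"{name}: {len(missing)} missing days inside span, first {missing[0].date()}"
            )
    return out


def split_contiguous(series: pd.Series) -> list[pd.Series]:
    """Split a daily series into maximal gap-free segments.

    Summer-block data carries no winter days; stages that require contiguous
    input (heatwave run detection) are applied per segment.
    """
    s = check_daily(series, "series")
    gaps = s.index.to_series().diff() > pd.Timedelta(days=1)
    return [seg for _, seg in s.groupby(gaps.cumsum())]


def check_deaths(series: pd.Series, name: str = "deaths") -> pd.Series:
    """Validate death counts: daily, finite, non-negative integers."""
    out = check_daily(series, name)
    arr = np.asarray(out, float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name}: non-finite values present")
    if np.any(arr < 0):
        raise ValueError(f"{name}: negative death counts present")
    if np.any(arr != np.round(arr)):
        raise ValueError(f"{name}: death counts must be integers")
    return out
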