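"""Comparing the two estimators region-by-heatwave and at national scale.

Paired estimates (surveillance excess vs DLNM attribution) are summarised
by a total-least-squares best-fit line (orthogonal distance regression via
the principal axis of the centred point cloud — both axes are deaths, so
errors are weighted equally), per-year national totals, and agreement flags
based on whether each method's central estimate lies inside the other's
95% interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .excess import MortalityEstimate, combine_estimates

__all__ = ["ComparisonRow", "odr_fit", "annual_totals", "agreement_report", "agreement_fraction"]


@dataclass(frozen=True)
class ComparisonRow:
    """One region × heatwave pair of estimates from the two methods."""

    region: str
    period: object
    ukhsa: MortalityEstimate
    dlnm: MortalityEstimate

    def __post_init__(self) -> None:
        if self.ukhsa.method == self.dlnm.method:
            raise ValueError("the two estimates must come from different methods")

    @property
    def overlap(self) -> bool:
        """Do the two 95% intervals intersect?"""
        return (
            self.ukhsa.ci_low <= self.dlnm.ci_high
            and self.dlnm.ci_low <= self.ukhsa.ci_high
        )

    @property
    def year(self) -> int:
        start = getattr(self.period, "start", self.period)
        try:
            return int(pd.Timestamp(start).year)
        except (ValueError, TypeError):
            return -1  # period label carries no date


def odr_fit(x, y) -> tuple[float, float]:
    """Total-least-squares line through a point cloud: (slope, intercept).

    Minimises summed squared perpendicular distances assuming equal error
    variance on both axes; the line is the principal axis of the centred
    cloud.  The slope is continuous with OLS for near-identity clouds.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two same-length 1-d vectors with ≥ 2 points")
    xc, yc = x - x.mean(), y - y.mean()
    cov = np.cov(np.vstack([xc, yc]))
    if np.allclose(cov, 0.0):
        raise ValueError("all points identical: no direction to fit")
    eigvals, eigvecs = np.linalg.eigh(cov)
    v = eigvecs[:, np.argmax(eigvals)]  # principal axis
    if v[0] == 0.0:
        raise ValueError("best-fit line is vertical; slope undefined")
    slope = float(v[1] / v[0])
    intercept = float(y.mean() - slope * x.mean())
    return slope, intercept


def _check_unique(rows: Sequence[ComparisonRow]) -> None:
    seen = set()
    for r in rows:
        key = (r.region, str(r.period))
        if key in seen:
            raise ValueError(f"duplicated (region, period) row: {key}")
        seen.add(key)


def annual_totals(
    rows: Sequence[ComparisonRow],
    year: int | None = None,
    dlnm_draw_totals: np.ndarray | None = None,
) -> tuple[MortalityEstimate, MortalityEstimate]:
    """National totals per method over the given year's rows.

    Centrals are summed; intervals combine in quadrature.  When per-draw
    DLNM totals are supplied (one column per row, one line per Monte Carlo
    draw, independent draws across regions), the DLNM interval is instead
    the empirical 95% interval of the summed draws — the exact alternative
    to the quadrature rule.
    """
    rows = [r for r in rows if year is None or r.year == year]
    if not rows:
        raise ValueError(f"no comparison rows for year {year}")
    _check_unique(rows)
    ukhsa_total = combine_estimates([r.ukhsa for r in rows])
    dlnm_total = combine_estimates([r.dlnm for r in rows])
    if dlnm_draw_totals is not None:
        if dlnm_draw_totals.shape[1] != len(rows):
            raise ValueError("one draw-total column per row required")
        sums = dlnm_draw_totals.sum(axis=1)
        central = dlnm_total.central
        lo, hi = np.percentile(sums, [2.5, 97.5])
        dlnm_total = MortalityEstimate(
            central=central,
            ci_low=float(min(lo, central)),
            ci_high=float(max(hi, central)),
            region=dlnm_total.region,
            period=dlnm_total.period,
            method="dlnm",
        )
    return ukhsa_total, dlnm_total


def agreement_report(rows: Sequence[ComparisonRow]) -> pd.DataFrame:
    """Row-level agreement table.

    Flags whether each method's central lies inside the other's 95%
    interval and whether the intervals overlap at all.
    """
    _check_unique(rows)
    records = []
    for r in rows:
        records.append(
            {
                "region": r.region,
                "year": r.year,
                "period": str(getattr(r.period, "start", r.period))[:10],
                "ukhsa_central": r.ukhsa.central,
                "dlnm_central": r.dlnm.central,
                "dlnm_in_ukhsa_ci": r.ukhsa.contains(r.dlnm.central),
                "ukhsa_in_dlnm_ci": r.dlnm.contains(r.ukhsa.central),
                "ci_overlap": r.overlap,
            }
        )
    return pd.DataFrame.from_records(records)


def agreement_fraction(pairs: Sequence[tuple[MortalityEstimate, MortalityEstimate]]) -> float:
    """Fraction of (ukhsa_total, dlnm_total) pairs where the DLNM central
    lies inside the surveillance estimate's 95% interval."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no annual totals supplied")
    hits = sum(1 for u, d in pairs if u.contains(d.central))
    return hits / len(pairs)
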