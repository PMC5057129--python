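"""Disturbance / decline classification of fitted trajectories.

An event is read off the fitted breakpoints, not raw observations: maximal
runs of consecutive negative-slope segments are merged into one candidate
event (cloud gaps often split a single drop into two fitted segments).  A
*disturbance* drops the index from above ``high_ndvi`` to below ``low_ndvi``
faster than ``rate_cut`` per year; the same crossing at a lower rate is a
*decline*; a run that never crosses both levels is no event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .segmentation import PiecewiseModel
from .timeseries import DAYS_PER_YEAR, ordinal_to_year

__all__ = [
    "Thresholds",
    "DisturbanceRecord",
    "classify_trajectory",
    "date_of_disturbance",
    "pixel_event_class",
    "cumulative_area",
    "annual_rate_correlation",
]

EVENT_DISTURBANCE = "disturbance"
EVENT_DECLINE = "decline"
EVENT_STABLE = "stable"
EVENT_NONE = "no_event"


@dataclass(frozen=True)
class Thresholds:
    """Event thresholds in NDVI units and NDVI/year.

    ``flat_slope`` is the loss-rate below which a fitted segment is treated
    as flat rather than declining when merging runs: fitted plateaus are
    almost never exactly level, and without the tolerance a steep drop would
    merge with a near-level, slightly tilted tail and push the apparent
    nadir to the end of the record.  0.01 NDVI/year (1 NDVI per century) is
    well below any meaningful decline.

    ``nadir_tol`` handles the same artifact inside a merged run: the nadir
    is the earliest breakpoint whose value is within this tolerance of the
    run minimum; fitted bottom-plateau breakpoints scatter by about this
    much, and the strict minimum would bias the event bottom late.
    """

    high_ndvi: float = 0.70
    low_ndvi: float = 0.40
    rate_cut: float = 0.10
    flat_slope: float = 0.01
    nadir_tol: float = 0.05

    def __post_init__(self):
        if not self.high_ndvi > self.low_ndvi:
            raise ValueError("high_ndvi must exceed low_ndvi")
        if self.rate_cut <= 0:
            raise ValueError("rate_cut must be positive")
        if not 0 <= self.flat_slope < self.rate_cut:
            raise ValueError("flat_slope must lie in [0, rate_cut)")
        if self.nadir_tol < 0:
            raise ValueError("nadir_tol must be >= 0")


@dataclass(frozen=True)
class DisturbanceRecord:
    """One classified declining run of a fitted trajectory."""

    date_before_disturbance: int
    date_of_nadir: int
    drop_rate: float          # NDVI per year over the merged declining span
    magnitude: float          # NDVI units lost from run start to nadir
    event_class: str
    recovered: bool


def classify_trajectory(model: PiecewiseModel,
                        thresholds: Thresholds = Thresholds()
                        ) -> List[DisturbanceRecord]:
    """Classify every merged declining run of the fitted trajectory."""
    bx, by = model.bx, model.by
    years = bx / DAYS_PER_YEAR
    slopes = np.diff(by) / np.diff(years)
    declining = slopes < -thresholds.flat_slope
    records: List[DisturbanceRecord] = []
    k = 0
    nseg = slopes.size
    while k < nseg:
        if not declining[k]:
            k += 1
            continue
        start = k
        while k < nseg and declining[k]:
            k += 1
        end = k                      # run covers breakpoints start..end
        run_min = by[start:end + 1].min()
        nadir = start + int(np.argmax(by[start:end + 1] <= run_min + thresholds.nadir_tol))
        start_val = by[start]
        nadir_val = by[nadir]
        span_years = years[nadir] - years[start]
        rate = (start_val - nadir_val) / span_years if span_years > 0 else np.inf
        crosses = start_val > thresholds.high_ndvi and nadir_val < thresholds.low_ndvi
        if crosses and rate > thresholds.rate_cut:
            klass = EVENT_DISTURBANCE
        elif crosses:
            klass = EVENT_DECLINE
        else:
            klass = EVENT_NONE
        # last breakpoint in the run still at/above the high level
        pre_idx = start
        for j in range(start, nadir + 1):
            if by[j] >= thresholds.high_ndvi:
                pre_idx = j
        recovered = any(
            by[j] > thresholds.low_ndvi and by[j] > by[j - 1]
            for j in range(nadir + 1, bx.size)
        )
        records.append(DisturbanceRecord(
            date_before_disturbance=int(bx[pre_idx]),
            date_of_nadir=int(bx[nadir]),
            drop_rate=float(rate),
            magnitude=float(start_val - nadir_val),
            event_class=klass,
            recovered=bool(recovered),
        ))
    return records


def date_of_disturbance(records: Iterable[DisturbanceRecord]) -> Optional[int]:
    """Nadir date of the first disturbance event, or None."""
    for rec in records:
        if rec.event_class == EVENT_DISTURBANCE:
            return rec.date_of_nadir
    return None


def pixel_event_class(records: Iterable[DisturbanceRecord]) -> str:
    """Single pixel-level label: disturbance > decline > stable."""
    classes = {rec.event_class for rec in records}
    if EVENT_DISTURBANCE in classes:
        return EVENT_DISTURBANCE
    if EVENT_DECLINE in classes:
        return EVENT_DECLINE
    return EVENT_STABLE


def cumulative_area(per_pixel_dates: Iterable, pixel_area_km2: float,
                    years: Optional[Iterable[int]] = None) -> pd.Series:
    """Cumulative disturbed area (km^2) at each calendar year end.

    ``per_pixel_dates`` holds one disturbance (nadir) ordinal day per
    disturbed pixel; None/NaN entries are undisturbed pixels.  The result is
    non-decreasing and bounded by n_pixels * pixel_area_km2.
    """
    if pixel_area_km2 <= 0:
        raise ValueError("pixel_area_km2 must be positive")
    dates = [d for d in per_pixel_dates if d is not None and np.isfinite(d)]
    if years is None:
        if not dates:
            return pd.Series(dtype=float, name="cumulative_km2")
        yr = ordinal_to_year(np.asarray(dates))
        years = range(int(np.min(yr)), int(np.max(yr)) + 1)
    years = list(years)
    event_years = np.asarray(ordinal_to_year(np.asarray(dates))) if dates else np.empty(0)
    counts = np.array([(event_years <= y).sum() for y in years])
    return pd.Series(counts * pixel_area_km2, index=pd.Index(years, name="year"),
                     name="cumulative_km2")


def annual_rate_correlation(yearly_disturbed_km2, yearly_production) -> float:
    """Pearson correlation of annual disturbance rates with production.

    Both inputs are annual series of equal length (rates, i.e. first
    differences of cumulative area, against e.g. annual ore production).
    """
    a = np.asarray(yearly_disturbed_km2, dtype=float)
    b = np.asarray(yearly_production, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need two equal-length series with n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a zero-variance series")
    return float(stats.pearsonr(a, b).statistic)
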