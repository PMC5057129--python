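"""Core data model for irregular spectral-index time series.

A pixel history is an irregularly sampled sequence of (date, index value)
pairs with a per-date validity flag.  Dates are stored as integer proleptic
Gregorian ordinal days (``datetime.date.toordinal``); rates expressed per
year use 365.25 days/year throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date as _date
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "DAYS_PER_YEAR",
    "InsufficientDataError",
    "DateAxis",
    "PixelSeries",
    "NITAParams",
    "compute_ndvi",
    "estimate_noise",
    "drop_invalid",
    "year_to_ordinal",
    "ordinal_to_year",
]

DAYS_PER_YEAR = 365.25


class InsufficientDataError(ValueError):
    """Raised when a pixel history has too few valid observations to fit."""


def year_to_ordinal(year: float) -> int:
    """Convert a decimal year (e.g. 1991.5) to an integer ordinal day."""
    whole = int(np.floor(year))
    return int(round(_date(whole, 1, 1).toordinal() + (year - whole) * DAYS_PER_YEAR))


def ordinal_to_year(ordinal: Union[int, np.ndarray]) -> Union[int, np.ndarray]:
    """Calendar year of an ordinal day (vectorised)."""
    if np.isscalar(ordinal):
        return _date.fromordinal(int(ordinal)).year
    return np.array([_date.fromordinal(int(o)).year for o in np.asarray(ordinal)])


@dataclass(frozen=True)
class DateAxis:
    """Strictly increasing observation dates in integer ordinal days."""

    dates: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.dates, dtype=np.int64)
        if d.ndim != 1:
            raise ValueError("DateAxis requires a 1-D array of dates")
        if d.size > 1 and np.any(np.diff(d) <= 0):
            raise ValueError("dates must be strictly increasing with no duplicates")
        object.__setattr__(self, "dates", d)

    def __len__(self) -> int:
        return int(self.dates.size)

    @property
    def year_fraction(self) -> np.ndarray:
        """Decimal-year view of the axis (ordinal days / 365.25)."""
        return self.dates / DAYS_PER_YEAR


@dataclass(frozen=True)
class PixelSeries:
    """One pixel's spectral-index history: dates, values, validity flags."""

    axis: DateAxis
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        m = np.asarray(self.valid, dtype=bool)
        if v.shape != self.axis.dates.shape or m.shape != self.axis.dates.shape:
            raise ValueError("values and valid must match the date axis length")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "valid", m)

    @classmethod
    def from_arrays(cls, dates, values, valid=None) -> "PixelSeries":
        values = np.asarray(values, dtype=float)
        if valid is None:
            valid = np.isfinite(values)
        return cls(DateAxis(np.asarray(dates)), values, np.asarray(valid, dtype=bool))

    @property
    def dates(self) -> np.ndarray:
        return self.axis.dates

    @property
    def n_obs(self) -> int:
        return len(self.axis)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def drop_invalid(self) -> "PixelSeries":
        return drop_invalid(self)

    # -- plain-text serialization (two columns: ordinal_day value) ----------
    def to_text(self, path: Union[str, Path]) -> None:
        """Write the valid observations as two whitespace-separated columns."""
        keep = self.drop_invalid()
        arr = np.column_stack([keep.dates, keep.values])
        np.savetxt(path, arr, fmt=["%d", "%.10g"], header="ordinal_day value")

    @classmethod
    def from_text(cls, path: Union[str, Path]) -> "PixelSeries":
        arr = np.atleast_2d(np.loadtxt(path))
        return cls.from_arrays(arr[:, 0].astype(np.int64), arr[:, 1])


@dataclass(frozen=True)
class NITAParams:
    """User-facing fitting parameters.

    Defaults are the algorithm's general-purpose settings; :meth:`study`
    returns the parameter set selected for the mining-disturbance study
    (prctile 90, bail_thresh 2, filt_dist 3, penalty 4).

    prctile
        Percentile of the local value window used for breakpoint values.
        Median (50) for symmetric noise; high values ride the upper envelope
        when contamination only depresses the index.
    bail_thresh
        A pixel keeps the single-segment fit when the ratio of initial fit
        error to series noise does not exceed this value.
    max_segment
        Maximum number of SEGMENTS grown in the build stage (breakpoints =
        segments + 1).
    filt_dist
        Radius, in observation indices, of the median filter applied to the
        error vector and of the knot value window.  0 disables filtering
        (single-point windows) — appropriate for noiseless data.
    penalty
        Multiplier on the BIC complexity term; larger values favour simpler
        models.
    xy_scale
        Years of x per unit of y for the orthogonal-distance geometry.
    """

    prctile: float = 50.0
    bail_thresh: float = 1.0
    max_segment: int = 10
    filt_dist: int = 3
    penalty: float = 1.0
    xy_scale: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.prctile <= 100.0:
            raise ValueError("prctile must lie in [0, 100]")
        if self.bail_thresh <= 0:
            raise ValueError("bail_thresh must be positive")
        if self.max_segment < 1:
            raise ValueError("max_segment must be a positive integer")
        if self.filt_dist < 0:
            raise ValueError("filt_dist must be a non-negative integer")
        if self.penalty <= 0:
            raise ValueError("penalty must be positive")
        if self.xy_scale <= 0:
            raise ValueError("xy_scale must be positive")

    @classmethod
    def study(cls, **overrides) -> "NITAParams":
        """The parameter set used for the disturbance mapping study."""
        base = dict(prctile=90.0, bail_thresh=2.0, max_segment=10,
                    filt_dist=3, penalty=4.0)
        base.update(overrides)
        return cls(**base)

    def replace(self, **changes) -> "NITAParams":
        return replace(self, **changes)


def compute_ndvi(red, nir):
    """Normalized difference vegetation index, (NIR - Red)/(NIR + Red).

    Accepts scalars or arrays of surface reflectance in [0, 1].  Dates where
    the denominator vanishes or an input is non-finite yield NaN (the caller
    marks those observations invalid).  Output is clipped to [-1, 1].
    """
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    if np.any(red[np.isfinite(red)] < 0) or np.any(nir[np.isfinite(nir)] < 0):
        raise ValueError("reflectances must be non-negative")
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (nir - red) / np.where(denom > 0, denom, 1.0), np.nan)
    out = np.clip(out, -1.0, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def estimate_noise(series: PixelSeries) -> float:
    """Series noise: median absolute forward difference of valid values.

    A single robust scalar internalising atmospheric contamination, geometric
    error and phenology.  Absolute differences are used so the statistic
    measures noise magnitude.
    """
    vals = series.values[series.valid]
    if vals.size < 2:
        raise InsufficientDataError("noise estimate needs >= 2 valid observations")
    return float(np.median(np.abs(np.diff(vals))))


def drop_invalid(series: PixelSeries) -> PixelSeries:
    """Sub-series of valid observations, order preserved. Idempotent."""
    keep = series.valid
    return PixelSeries(
        DateAxis(series.dates[keep]),
        series.values[keep],
        np.ones(int(keep.sum()), dtype=bool),
    )
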