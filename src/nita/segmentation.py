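"""Noise-insensitive piecewise-linear trajectory fitting.

The fitter approximates an irregular index time series with a continuous
piecewise-linear model whose vertices ("breakpoints") sit on observation
dates.  It proceeds in two stages:

*build*
    Starting from a single segment between the first and last observation,
    breakpoints are inserted greedily at the date of maximum median-filtered
    orthogonal error of the current fit, with the breakpoint value taken as a
    percentile of the values in a local window (robust to asymmetric,
    cloud-like contamination).

*subtract*
    Superfluous breakpoints are removed by greedy backward elimination under
    a Bayesian Information Criterion whose likelihood treats the orthogonal
    distances as lognormal.

Orthogonal distances are measured in a rescaled plane where the date axis is
expressed in years (divided by ``xy_scale``) so that the two axes are
commensurate with index units.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .timeseries import (
    DAYS_PER_YEAR,
    InsufficientDataError,
    NITAParams,
    PixelSeries,
    drop_invalid,
    estimate_noise,
)

__all__ = [
    "Breakpoint",
    "PiecewiseModel",
    "knot_value",
    "interpolate",
    "orthogonal_distances",
    "initial_fit",
    "bail_check",
    "nita_build",
    "lognormal_loglik",
    "bic",
    "nita_subtract",
    "fit_pixel",
]

_DIST_FLOOR = 1e-6
_SIGMA_FLOOR = 1e-6
_ZERO_TOL = 1e-12
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class Breakpoint:
    """A vertex of the piecewise-linear model: (ordinal day, index value)."""

    date: int
    value: float


@dataclass(frozen=True)
class PiecewiseModel:
    """A fitted piecewise-linear trajectory plus its fit diagnostics.

    ``bx``/``by`` are the ordered breakpoint dates (ordinal days) and values,
    including the two endpoints.  ``distances`` holds the per-observation
    orthogonal distances of the series the model was fitted to.
    """

    bx: np.ndarray
    by: np.ndarray
    distances: np.ndarray
    noise: float
    loglik: float
    n_obs: int
    bic: float

    def __post_init__(self):
        bx = np.asarray(self.bx, dtype=np.int64)
        by = np.asarray(self.by, dtype=float)
        if bx.size != by.size or bx.size < 2:
            raise ValueError("model needs >= 2 breakpoints with matching values")
        if np.any(np.diff(bx) <= 0):
            raise ValueError("breakpoint dates must be strictly increasing")
        if not np.all(np.isfinite(by)):
            raise ValueError("breakpoint values must be finite")
        object.__setattr__(self, "bx", bx)
        object.__setattr__(self, "by", by)
        object.__setattr__(self, "distances", np.asarray(self.distances, dtype=float))

    @property
    def breakpoints(self) -> list:
        return [Breakpoint(int(d), float(v)) for d, v in zip(self.bx, self.by)]

    @property
    def segments(self) -> int:
        return int(self.bx.size - 1)

    def __call__(self, dates) -> np.ndarray:
        return interpolate(self, dates)

    # -- plain-text model dump ---------------------------------------------
    def to_text(self, path: Union[str, Path, None] = None) -> str:
        buf = io.StringIO()
        buf.write(f"# segments={self.segments} bic={self.bic:.10g} "
                  f"noise={self.noise:.10g} loglik={self.loglik:.10g} "
                  f"n_obs={self.n_obs}\n")
        for d, v in zip(self.bx, self.by):
            buf.write(f"{int(d)} {v:.10g}\n")
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_text(cls, source: Union[str, Path]) -> "PiecewiseModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        lines = [ln for ln in text.splitlines() if ln.strip()]
        meta = dict(kv.split("=") for kv in lines[0].lstrip("# ").split())
        rows = np.array([[float(t) for t in ln.split()] for ln in lines[1:]])
        return cls(rows[:, 0].astype(np.int64), rows[:, 1],
                   np.empty(0), float(meta["noise"]), float(meta["loglik"]),
                   int(meta["n_obs"]), float(meta["bic"]))


def knot_value(series: PixelSeries, center_index: int, prctile: float,
               filt_dist: int, positions: np.ndarray | None = None) -> float:
    """Percentile of the values within +/- ``filt_dist`` of the centre.

    The window is measured along the acquisition calendar: ``positions``
    holds each valid observation's position in the full image-date calendar
    (cloud-gapped pixels have fewer points per window).  When ``positions``
    is omitted the observations are taken as consecutive calendar dates and
    the window is +/- ``filt_dist`` observation indices, clipped to the
    series bounds.  Percentiles use the linear-interpolation definition;
    the window always contains at least the centre point.
    """
    vals = series.values
    n = vals.size
    if not 0 <= center_index < n:
        raise IndexError("center_index outside the series")
    if positions is None:
        lo = max(0, center_index - filt_dist)
        hi = min(n, center_index + filt_dist + 1)
        return float(np.percentile(vals[lo:hi], prctile))
    inside = np.abs(positions - positions[center_index]) <= filt_dist
    return float(np.percentile(vals[inside], prctile))


def interpolate(model: PiecewiseModel, dates) -> np.ndarray:
    """Piecewise-linear evaluation of the model; exact at breakpoints."""
    d = np.asarray(dates, dtype=float)
    if np.any(d < model.bx[0]) or np.any(d > model.bx[-1]):
        raise ValueError("date outside the model span")
    out = np.interp(d, model.bx, model.by)
    return float(out) if out.ndim == 0 else out


def _polyline_distances(bx, by, x, y, xy_scale: float) -> np.ndarray:
    """Perpendicular distance of each (x, y) to the nearest polyline segment.

    x and bx are ordinal days; internally converted to years / xy_scale so
    both axes are commensurate.
    """
    sx = np.asarray(x, dtype=float) / (DAYS_PER_YEAR * xy_scale)
    sbx = np.asarray(bx, dtype=float) / (DAYS_PER_YEAR * xy_scale)
    by = np.asarray(by, dtype=float)
    dx = np.diff(sbx)              # (K-1,)
    dy = np.diff(by)
    L2 = dx * dx + dy * dy
    L2 = np.where(L2 > 0, L2, 1.0)
    px = sx[:, None] - sbx[None, :-1]      # (N, K-1)
    py = np.asarray(y, dtype=float)[:, None] - by[None, :-1]
    t = np.clip((px * dx + py * dy) / L2, 0.0, 1.0)
    ex = px - t * dx
    ey = py - t * dy
    return np.sqrt(np.min(ex * ex + ey * ey, axis=1))


def orthogonal_distances(model: PiecewiseModel, series: PixelSeries,
                         xy_scale: float = 1.0) -> np.ndarray:
    """Orthogonal distances of a series' valid observations to the model."""
    s = drop_invalid(series)
    return _polyline_distances(model.bx, model.by, s.dates, s.values, xy_scale)


def _median_filter(values: np.ndarray, filt_dist: int,
                   positions: np.ndarray | None = None) -> np.ndarray:
    """1-D median filter over +/- ``filt_dist`` calendar positions,
    edge-truncated (index window when ``positions`` is None)."""
    if filt_dist <= 0:
        return values
    n = values.size
    out = np.empty(n)
    if positions is None:
        for i in range(n):
            out[i] = np.median(values[max(0, i - filt_dist):i + filt_dist + 1])
        return out
    lo = np.searchsorted(positions, positions - filt_dist, side="left")
    hi = np.searchsorted(positions, positions + filt_dist, side="right")
    for i in range(n):
        out[i] = np.median(values[lo[i]:hi[i]])
    return out


def lognormal_loglik(distances: np.ndarray) -> float:
    """Lognormal log-likelihood of the distances at their own MLE.

    Distances are floored at 1e-6 before taking logs; the MLE uses the
    population (1/n) standard deviation of the log-distances, itself floored
    at 1e-6 so degenerate spreads stay finite.
    """
    d = np.maximum(np.asarray(distances, dtype=float), _DIST_FLOOR)
    if d.size == 0:
        raise ValueError("distances must be non-empty")
    ld = np.log(d)
    mu = ld.mean()
    sigma = max(ld.std(), _SIGMA_FLOOR)
    z = (ld - mu) / sigma
    return float(np.sum(-ld - np.log(sigma) - _LOG_SQRT_2PI - 0.5 * z * z))


def bic(loglik: float, segments: int, n_obs: int, penalty: float) -> float:
    """Complexity-penalised information criterion: penalty*segs*ln(N) - 2*logL."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return penalty * segments * np.log(n_obs) - 2.0 * loglik


def _finalize(bx, by, x, y, noise: float, params: NITAParams) -> PiecewiseModel:
    dist = _polyline_distances(bx, by, x, y, params.xy_scale)
    ll = lognormal_loglik(dist)
    return PiecewiseModel(bx, by, dist, noise, ll, x.size,
                          bic(ll, len(bx) - 1, x.size, params.penalty))


def initial_fit(series: PixelSeries, params: NITAParams,
                noise: float = np.nan) -> PiecewiseModel:
    """Single-segment fit anchored at percentile knots of the edge windows.

    The two anchor knots use the first and last ``filt_dist + 1`` valid
    observations (index windows) rather than the temporal kernel: they fix
    the whole fit's ends, and a calendar window at a gappy series edge can
    degenerate to a single, possibly contaminated, point.
    """
    s = drop_invalid(series)
    if s.n_obs < 2:
        raise InsufficientDataError("initial fit needs >= 2 valid observations")
    x, y = s.dates, s.values
    bx = np.array([x[0], x[-1]], dtype=np.int64)
    by = np.array([
        knot_value(s, 0, params.prctile, params.filt_dist),
        knot_value(s, s.n_obs - 1, params.prctile, params.filt_dist),
    ])
    return _finalize(bx, by, x, y, noise, params)


def bail_check(model: PiecewiseModel, noise: float, bail_thresh: float) -> bool:
    """True when the single-segment fit should be adopted outright.

    The fit error (mean orthogonal distance) is compared with the series
    noise; a ratio not exceeding ``bail_thresh`` means the extra structure a
    multi-segment model could capture is indistinguishable from noise.
    """
    if noise < 0:
        raise ValueError("noise must be non-negative")
    fit_error = float(np.mean(model.distances))
    if noise == 0.0:
        return fit_error <= _ZERO_TOL
    return (fit_error / noise) <= bail_thresh


def nita_build(series: PixelSeries, params: NITAParams,
               noise: float = np.nan) -> PiecewiseModel:
    """Grow breakpoints at maxima of the median-filtered orthogonal error.

    Starting from the single-segment fit, repeatedly insert a breakpoint at
    the observation date of maximum filtered error among dates that are not
    already breakpoints, until ``max_segment`` segments are reached or no
    eligible candidate remains.  Ties go to the earliest date.
    """
    pos = np.flatnonzero(series.valid)
    s = drop_invalid(series)
    if s.n_obs < 3:
        raise InsufficientDataError("build needs >= 3 valid observations")
    x, y = s.dates, s.values
    model = initial_fit(series, params, noise)
    bx, by = model.bx, model.by
    dist = model.distances
    bp_dates = set(bx.tolist())
    while (len(bx) - 1) < params.max_segment:
        filtered = _median_filter(dist, params.filt_dist, pos)
        eligible = np.fromiter((d not in bp_dates for d in x.tolist()),
                               dtype=bool, count=x.size)
        if not eligible.any():
            break
        masked = np.where(eligible, filtered, -np.inf)
        idx = int(np.argmax(masked))   # first occurrence = earliest date
        new_date = int(x[idx])
        new_val = knot_value(s, idx, params.prctile, params.filt_dist, pos)
        at = int(np.searchsorted(bx, new_date))
        bx = np.insert(bx, at, new_date)
        by = np.insert(by, at, new_val)
        bp_dates.add(new_date)
        dist = _polyline_distances(bx, by, x, y, params.xy_scale)
    ll = lognormal_loglik(dist)
    return PiecewiseModel(bx, by, dist, noise, ll, x.size,
                          bic(ll, len(bx) - 1, x.size, params.penalty))


def nita_subtract(model: PiecewiseModel, series: PixelSeries,
                  params: NITAParams) -> PiecewiseModel:
    """Greedy backward elimination of breakpoints under the BIC.

    Each round removes the single interior breakpoint whose deletion lowers
    the BIC the most; stops when no removal improves it.  Endpoints are never
    removed and surviving breakpoint values are not re-estimated.
    """
    s = drop_invalid(series)
    x, y = s.dates, s.values
    bx, by = model.bx, model.by
    dist = _polyline_distances(bx, by, x, y, params.xy_scale)
    ll = lognormal_loglik(dist)
    cur_bic = bic(ll, len(bx) - 1, x.size, params.penalty)
    while len(bx) > 2:
        best = None
        for j in range(1, len(bx) - 1):
            tbx = np.delete(bx, j)
            tby = np.delete(by, j)
            tdist = _polyline_distances(tbx, tby, x, y, params.xy_scale)
            tll = lognormal_loglik(tdist)
            tbic = bic(tll, len(tbx) - 1, x.size, params.penalty)
            if best is None or tbic < best[0]:
                best = (tbic, tbx, tby, tdist, tll)
        if best is None or best[0] >= cur_bic:
            break
        cur_bic, bx, by, dist, ll = best
    return PiecewiseModel(bx, by, dist, model.noise, ll, x.size, cur_bic)


def fit_pixel(series: PixelSeries, params: NITAParams = NITAParams()) -> PiecewiseModel:
    """Fit one pixel history: noise estimate, bail-out gate, build, subtract.

    Deterministic for fixed inputs.  Raises :class:`InsufficientDataError`
    below two valid observations.
    """
    s = drop_invalid(series)
    if s.n_obs < 2:
        raise InsufficientDataError("fit needs >= 2 valid observations")
    noise = estimate_noise(s)
    first = initial_fit(series, params, noise)
    if s.n_obs < 3 or bail_check(first, noise, params.bail_thresh):
        return first
    built = nita_build(series, params, noise)
    return nita_subtract(built, s, params)
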