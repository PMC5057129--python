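"""Scene-stack ingestion, per-pixel fitting dispatch, and map output.

A :class:`SceneStack` holds co-gridded red/NIR reflectance and mask rasters
for a list of acquisition dates.  Rasters are read and written as TIFF via
``tifffile`` with a small JSON sidecar (``<name>.meta.json``) carrying the
grid transform, CRS string and nodata value; round-trips are bit-exact.
Mask rasters use integer class codes with a configurable valid/invalid
mapping (the default follows the common clear/water/shadow/snow/cloud/fill
convention).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from datetime import date as _date, datetime
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import tifffile

from .classify import (EVENT_DECLINE, EVENT_DISTURBANCE, EVENT_STABLE,
                       Thresholds, classify_trajectory, date_of_disturbance,
                       pixel_event_class)
from .segmentation import fit_pixel
from .timeseries import (InsufficientDataError, NITAParams, PixelSeries,
                         compute_ndvi)

__all__ = [
    "GridMeta",
    "MaskPolicy",
    "Scene",
    "SceneStack",
    "load_stack",
    "extract_series",
    "fit_image",
    "write_map",
    "read_map",
    "parse_scene_date",
]

logger = logging.getLogger("nita.raster")

#: map nodata / event-class codes
CLASS_CODES = {EVENT_STABLE: 1, EVENT_DECLINE: 2, EVENT_DISTURBANCE: 3}
NODATA = 0


@dataclass(frozen=True)
class GridMeta:
    """Minimal georeferencing: affine transform (GDAL order) + CRS string."""

    transform: Tuple[float, float, float, float, float, float] = (0, 1, 0, 0, 0, -1)
    crs: str = ""
    nodata: float = NODATA


@dataclass(frozen=True)
class MaskPolicy:
    """Mapping from integer mask codes to validity.

    Default: clear (0) and water (1) valid; shadow (2), snow (3), cloud (4)
    and fill (255) invalid.  Codes missing from the mapping are invalid.
    """

    valid_codes: frozenset = frozenset({0, 1})

    def is_valid(self, mask: np.ndarray) -> np.ndarray:
        return np.isin(mask, sorted(self.valid_codes))


_SCENE_ID_PATTERNS = (
    re.compile(r"(?:^|_)(\d{8})(?:_|$)"),               # collection ids: ..._YYYYMMDD_...
    re.compile(r"^L[A-Z]\d{7}(\d{4})(\d{3})"),          # legacy ids: LT51030631991166...
)


def parse_scene_date(scene_id: str) -> int:
    """Ordinal day parsed from a standard Landsat scene identifier."""
    m = _SCENE_ID_PATTERNS[0].search(scene_id)
    if m:
        return datetime.strptime(m.group(1), "%Y%m%d").date().toordinal()
    m = _SCENE_ID_PATTERNS[1].search(scene_id)
    if m:
        year, doy = int(m.group(1)), int(m.group(2))
        return _date(year, 1, 1).toordinal() + doy - 1
    raise ValueError(f"cannot parse a date from scene id {scene_id!r}")


@dataclass(frozen=True)
class Scene:
    """One acquisition: date plus co-gridded band and mask arrays."""

    date: int
    red: np.ndarray
    nir: np.ndarray
    mask: np.ndarray


@dataclass(frozen=True)
class SceneStack:
    """Date-sorted scenes on a common grid with per-pixel validity."""

    dates: np.ndarray          # (T,) ordinal days, sorted unique
    red: np.ndarray            # (T, rows, cols)
    nir: np.ndarray
    valid: np.ndarray          # (T, rows, cols) bool
    grid: GridMeta = GridMeta()

    def __post_init__(self):
        if not (self.red.shape == self.nir.shape == self.valid.shape):
            raise ValueError("band/mask arrays must share one grid shape")
        if self.red.shape[0] != self.dates.size:
            raise ValueError("one scene per date required")
        if np.any(np.diff(self.dates) <= 0):
            raise ValueError("scene dates must be unique and sorted")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.red.shape[1:]

    @classmethod
    def from_scenes(cls, scenes: Iterable[Scene],
                    mask_policy: MaskPolicy = MaskPolicy(),
                    grid: GridMeta = GridMeta()) -> "SceneStack":
        scenes = sorted(scenes, key=lambda s: s.date)
        shapes = {s.red.shape for s in scenes} | {s.nir.shape for s in scenes} \
            | {s.mask.shape for s in scenes}
        if len(shapes) != 1:
            raise ValueError(f"scenes are not on a common grid: {sorted(shapes)}")
        dates = np.array([s.date for s in scenes], dtype=np.int64)
        red = np.stack([s.red.astype(float) for s in scenes])
        nir = np.stack([s.nir.astype(float) for s in scenes])
        valid = np.stack([mask_policy.is_valid(s.mask) for s in scenes])
        valid &= np.isfinite(red) & np.isfinite(nir)
        return cls(dates, red, nir, valid, grid)


def load_stack(entries: Sequence[dict],
               mask_policy: MaskPolicy = MaskPolicy(),
               dates_csv: Optional[Union[str, Path]] = None,
               grid: GridMeta = GridMeta()) -> SceneStack:
    """Read a stack from disk.

    ``entries`` is a list of dicts with keys ``scene_id``, ``red``, ``nir``,
    ``mask`` (paths to single-band TIFFs).  Dates come from the scene id, or
    from a sidecar CSV (scene_id,date columns; ISO dates) that overrides the
    id-derived date — useful for synthetic fixtures.
    """
    overrides: Dict[str, int] = {}
    if dates_csv is not None:
        import pandas as pd
        df = pd.read_csv(dates_csv)
        overrides = {
            str(r["scene_id"]): datetime.fromisoformat(str(r["date"])).toordinal()
            for _, r in df.iterrows()
        }
    scenes = []
    for e in entries:
        sid = str(e["scene_id"])
        day = overrides.get(sid)
        if day is None:
            day = parse_scene_date(sid)
        scenes.append(Scene(
            date=day,
            red=tifffile.imread(e["red"]),
            nir=tifffile.imread(e["nir"]),
            mask=tifffile.imread(e["mask"]),
        ))
    return SceneStack.from_scenes(scenes, mask_policy, grid)


def extract_series(stack: SceneStack, row: int, col: int) -> PixelSeries:
    """NDVI time series of one pixel, with validity from the mask policy."""
    red = stack.red[:, row, col]
    nir = stack.nir[:, row, col]
    ndvi = compute_ndvi(np.where(np.isfinite(red) & (red >= 0), red, np.nan),
                        np.where(np.isfinite(nir) & (nir >= 0), nir, np.nan))
    valid = stack.valid[:, row, col] & np.isfinite(ndvi)
    return PixelSeries.from_arrays(stack.dates, np.where(valid, ndvi, np.nan), valid)


def fit_image(stack: SceneStack,
              params: NITAParams = NITAParams(),
              thresholds: Thresholds = Thresholds()) -> Dict[str, np.ndarray]:
    """Fit every pixel and derive the study's map products.

    Returns 2-D arrays ``date_of_disturbance`` (ordinal day of the first
    disturbance nadir; 0 = none/nodata), ``segments`` (fitted segment count;
    0 = nodata) and ``event_class`` (0 nodata, 1 stable, 2 decline, 3
    disturbance).  Pixels with fewer than two valid dates emit nodata;
    per-pixel failures are logged and nodata-filled.  Deterministic,
    single-process, row-major order.
    """
    rows, cols = stack.shape
    dod = np.zeros((rows, cols), dtype=np.int32)
    segs = np.zeros((rows, cols), dtype=np.int16)
    klass = np.zeros((rows, cols), dtype=np.uint8)
    for r in range(rows):
        for c in range(cols):
            try:
                series = extract_series(stack, r, c)
                model = fit_pixel(series, params)
            except InsufficientDataError:
                continue
            except Exception:                     # pragma: no cover
                logger.exception("pixel (%d, %d) failed; writing nodata", r, c)
                continue
            records = classify_trajectory(model, thresholds)
            segs[r, c] = model.segments
            klass[r, c] = CLASS_CODES[pixel_event_class(records)]
            day = date_of_disturbance(records)
            if day is not None:
                dod[r, c] = day
        logger.debug("fit_image: finished row %d/%d", r + 1, rows)
    return {"date_of_disturbance": dod, "segments": segs, "event_class": klass}


def write_map(path: Union[str, Path], array: np.ndarray,
              grid: GridMeta = GridMeta()) -> None:
    """Write a single-band map as TIFF plus a JSON georeferencing sidecar."""
    path = Path(path)
    tifffile.imwrite(path, array)
    sidecar = {"transform": list(grid.transform), "crs": grid.crs,
               "nodata": grid.nodata, "dtype": str(array.dtype)}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(sidecar, indent=1))


def read_map(path: Union[str, Path]) -> Tuple[np.ndarray, GridMeta]:
    """Read a map written by :func:`write_map`; bit-exact round trip."""
    path = Path(path)
    array = tifffile.imread(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    grid = GridMeta()
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        grid = GridMeta(tuple(meta["transform"]), meta["crs"], meta["nodata"])
    return array, grid
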