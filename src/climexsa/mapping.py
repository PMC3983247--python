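"""Area accounting, change maps and occurrence validation.

Cell areas are latitude-aware: a lat/lon cell is a spherical band sector,
``R^2 * dlon * (sin(lat_n) - sin(lat_s))`` with the authalic Earth radius
R = 6371 km, so category areas in km^2 weight poleward cells correctly.
Points are assigned to cells with a half-open [west, east) x [south, north)
rule, which partitions the plane deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .ecoclimatic import Category
from .grid import GridSpec

__all__ = [
    "EARTH_RADIUS_KM",
    "cell_area_km2",
    "category_areas",
    "CategoryAreas",
    "change_map",
    "ChangeMap",
    "filter_occurrences",
    "occurrence_category_counts",
    "ValidationCounts",
]

EARTH_RADIUS_KM = 6371.0

_CATEGORY_LABELS = ["unsuitable", "marginal", "suitable", "highly_suitable"]


def cell_area_km2(lat_center, resolution: float):
    """Area in km^2 of a grid cell centred at ``lat_center`` degrees."""
    lat = np.asarray(lat_center, dtype=float)
    half = resolution / 2.0
    if np.any(np.abs(lat) + half > 90.0 + 1e-9):
        raise ValueError("cell extends beyond a pole")
    dlon = np.deg2rad(resolution)
    band = np.sin(np.deg2rad(lat + half)) - np.sin(np.deg2rad(lat - half))
    return EARTH_RADIUS_KM**2 * dlon * band


@dataclass(frozen=True)
class CategoryAreas:
    """Per-category areas in km^2; no-data cells are excluded from total."""

    unsuitable: float
    marginal: float
    suitable: float
    highly_suitable: float

    @property
    def total(self) -> float:
        return self.unsuitable + self.marginal + self.suitable + self.highly_suitable

    @property
    def suitable_or_better(self) -> float:
        """The response used by the sensitivity analysis."""
        return self.suitable + self.highly_suitable

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in _CATEGORY_LABELS} | {"total": self.total}


def _cell_area_grid(raster: xr.Dataset) -> np.ndarray:
    lats = np.asarray(raster["lat"].values, dtype=float)
    res = float(raster.attrs.get("resolution", 0) or 0)
    if res <= 0:
        # fall back to coordinate spacing
        res = float(np.diff(lats).mean()) if lats.size > 1 else 0.5
    areas = cell_area_km2(lats, res)
    return np.broadcast_to(areas[:, None], raster["category"].shape)


def category_areas(raster: xr.Dataset) -> CategoryAreas:
    """Sum cell areas per suitability category of an EI raster."""
    cat = raster["category"].values
    areas = _cell_area_grid(raster)
    out = {}
    for c, label in zip(
        (Category.UNSUITABLE, Category.MARGINAL, Category.SUITABLE, Category.HIGHLY_SUITABLE),
        _CATEGORY_LABELS,
    ):
        out[label] = float(areas[cat == int(c)].sum())
    return CategoryAreas(**out)


@dataclass(frozen=True)
class ChangeMap:
    """Cellwise category transitions between a baseline and an adjusted run."""

    pairs: np.ndarray           # (nlat, nlon, 2) int8 baseline/adjusted categories
    counts: pd.DataFrame        # 4x4 transition counts, baseline rows
    areas: pd.DataFrame         # 4x4 transition areas km^2

    @property
    def unchanged_area(self) -> float:
        return float(np.diag(self.areas.values).sum())


def change_map(baseline: xr.Dataset, adjusted: xr.Dataset) -> ChangeMap:
    """Pair up categories cell by cell and tabulate 4x4 transitions."""
    if baseline["category"].shape != adjusted["category"].shape or not (
        np.allclose(baseline["lat"].values, adjusted["lat"].values)
        and np.allclose(baseline["lon"].values, adjusted["lon"].values)
    ):
        raise ValueError("baseline and adjusted rasters are on different grids")
    b = baseline["category"].values
    a = adjusted["category"].values
    areas = _cell_area_grid(baseline)
    counts = np.zeros((4, 4), dtype=int)
    area_tab = np.zeros((4, 4))
    valid = (b >= 0) & (a >= 0)
    for i in range(4):
        for j in range(4):
            mask = valid & (b == i) & (a == j)
            counts[i, j] = int(mask.sum())
            area_tab[i, j] = float(areas[mask].sum())
    idx = pd.Index(_CATEGORY_LABELS, name="baseline")
    cols = pd.Index(_CATEGORY_LABELS, name="adjusted")
    return ChangeMap(
        pairs=np.stack([b, a], axis=-1),
        counts=pd.DataFrame(counts, index=idx, columns=cols),
        areas=pd.DataFrame(area_tab, index=idx, columns=cols),
    )


def filter_occurrences(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop records lacking either coordinate.

    Returns ``(retained, removal_log)``; both preserve input order. The log
    has columns ``id, reason``.
    """
    if records.empty:
        empty_log = pd.DataFrame(columns=["id", "reason"])
        return records.copy(), empty_log
    lat = pd.to_numeric(records["lat"], errors="coerce")
    lon = pd.to_numeric(records["lon"], errors="coerce")
    missing = lat.isna() | lon.isna()
    bad_range = ~missing & ((lat.abs() > 90) | (lon.abs() > 180))
    drop = missing | bad_range
    reasons = np.where(missing, "missing coordinates", "coordinates out of range")
    log = pd.DataFrame({"id": records.loc[drop, "id"], "reason": reasons[drop]})
    return records.loc[~drop].copy(), log.reset_index(drop=True)


@dataclass(frozen=True)
class ValidationCounts:
    """Occurrence records per suitability category plus bookkeeping bins."""

    per_category: dict[str, int]
    out_of_grid: int
    missing_coords: int

    @property
    def total(self) -> int:
        return sum(self.per_category.values()) + self.out_of_grid + self.missing_coords


def occurrence_category_counts(
    records: pd.DataFrame, raster: xr.Dataset, spec: GridSpec | None = None
) -> ValidationCounts:
    """Count retained occurrence records per suitability category.

    Records without coordinates are tallied separately (so the raw table can
    be passed directly); records outside the grid extent likewise.
    """
    lats = np.asarray(raster["lat"].values, dtype=float)
    lons = np.asarray(raster["lon"].values, dtype=float)
    if spec is None:
        res = float(raster.attrs.get("resolution", 0) or 0)
        if res <= 0:
            res = float(np.diff(lats).mean()) if lats.size > 1 else 0.5
        spec = GridSpec(
            lat_min=float(lats[0] - res / 2), lat_max=float(lats[-1] + res / 2),
            lon_min=float(lons[0] - res / 2), lon_max=float(lons[-1] + res / 2),
            resolution=res,
        )
    cat = raster["category"].values
    per = {label: 0 for label in _CATEGORY_LABELS + ["nodata"]}
    out_of_grid = 0
    missing = 0
    for _, row in records.iterrows():
        lat, lon = row["lat"], row["lon"]
        if pd.isna(lat) or pd.isna(lon):
            missing += 1
            continue
        idx = spec.cell_index(float(lat), float(lon))
        if idx is None:
            out_of_grid += 1
            continue
        c = int(cat[idx])
        per["nodata" if c < 0 else _CATEGORY_LABELS[c]] += 1
    return ValidationCounts(per_category=per, out_of_grid=out_of_grid, missing_coords=missing)
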