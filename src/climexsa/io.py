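"""File formats: parameter files, climate NetCDF, rasters, occurrence CSV.

Species parameters travel as flat ``key=value`` text files using the
standard parameter codes, so parameter sets diff cleanly across screening
runs.  Gridded data are NetCDF (classic format, written through xarray's
scipy backend so no extra NetCDF library is required).  EI rasters can also
be written as GeoTIFF (float EI page + byte category page, WGS84 geographic
tags) through a minimal tag writer on top of tifffile.  CSVs use '.' as the
decimal separator and UTF-8 regardless of locale.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import fields
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .ecoclimatic import SpeciesParameters
from .grid import GridSpec

__all__ = [
    "read_species_parameters",
    "write_species_parameters",
    "save_netcdf",
    "load_netcdf",
    "write_geotiff",
    "read_occurrences",
    "write_occurrences",
    "config_hash",
]

_PARAM_CODES = [f.name for f in fields(SpeciesParameters)]


def read_species_parameters(path) -> SpeciesParameters:
    """Read a flat key=value parameter file.

    Unknown keys and missing keys are errors; ordering invariants are
    validated on construction (the error message names both knots).
    """
    values: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in _PARAM_CODES:
            raise ValueError(f"{path}:{lineno}: unknown parameter code {key!r}")
        if key in values:
            raise ValueError(f"{path}:{lineno}: duplicate parameter code {key!r}")
        try:
            values[key] = float(val.strip())
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric value for {key}") from exc
    missing = [c for c in _PARAM_CODES if c not in values]
    if missing:
        raise ValueError(f"{path}: missing parameter codes: {', '.join(missing)}")
    return SpeciesParameters(**values)


def write_species_parameters(p: SpeciesParameters, path) -> None:
    lines = [f"{code}={getattr(p, code):g}" for code in _PARAM_CODES]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def save_netcdf(ds: xr.Dataset | xr.DataArray, path, seed: int | None = None) -> None:
    """Write a dataset as classic NetCDF; int8 category data are widened
    (the classic format stores bytes but signed NaN-free handling is
    simpler in int16)."""
    if isinstance(ds, xr.DataArray):
        ds = ds.to_dataset()
    ds = ds.copy()
    if seed is not None:
        ds.attrs["seed"] = int(seed)
    for name, var in ds.data_vars.items():
        if var.dtype == np.int8:
            ds[name] = var.astype(np.int16)
    ds.to_netcdf(path, engine="scipy")


def load_netcdf(path) -> xr.Dataset:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()


def _geokeys_wgs84() -> list[tuple]:
    # GeoTIFF keys: GTModelTypeGeoKey=2 (geographic), GTRasterTypeGeoKey=1
    # (pixel-is-area), GeographicTypeGeoKey=4326 (WGS84).
    directory = [
        1, 1, 0, 3,
        1024, 0, 1, 2,
        1025, 0, 1, 1,
        2048, 0, 1, 4326,
    ]
    return [(34735, "H", len(directory), tuple(directory), True)]


def write_geotiff(raster: xr.Dataset, path, spec: GridSpec | None = None) -> None:
    """Write an EI raster as a two-page GeoTIFF (float32 EI, int8 category).

    Rows are flipped north-up as image conventions expect; WGS84 geographic
    referencing is attached via ModelPixelScale / ModelTiepoint tags.
    """
    import tifffile

    lats = np.asarray(raster["lat"].values, dtype=float)
    lons = np.asarray(raster["lon"].values, dtype=float)
    res = float(raster.attrs.get("resolution", 0) or 0)
    if res <= 0:
        res = float(np.diff(lats).mean()) if lats.size > 1 else 0.5
    north = lats.max() + res / 2.0
    west = lons.min() - res / 2.0
    extratags = _geokeys_wgs84() + [
        (33550, "d", 3, (res, res, 0.0), True),             # ModelPixelScaleTag
        (33922, "d", 6, (0.0, 0.0, 0.0, west, north, 0.0), True),  # ModelTiepointTag
    ]
    ei = np.flipud(raster["EI"].values.astype(np.float32))
    cat = np.flipud(raster["category"].values.astype(np.int8))
    with tifffile.TiffWriter(path) as tif:
        tif.write(ei, extratags=extratags, description="ecoclimatic index (0-100)")
        tif.write(cat, extratags=extratags, description="suitability category (-1..3)")


def read_occurrences(path) -> pd.DataFrame:
    """Read an occurrence CSV with header id,lat,lon,source.

    Malformed coordinate fields become missing coordinates; short rows are
    reported (with line number) and skipped.
    """
    df = pd.read_csv(path, dtype={"id": str, "source": str}, skip_blank_lines=True)
    required = {"id", "lat", "lon"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: occurrence CSV must have columns id, lat, lon")
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    if "source" not in df:
        df["source"] = ""
    return df.reset_index(drop=True)


def write_occurrences(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, float_format="%.4f")


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping, for artifact metadata."""
    blob = json.dumps(config, sort_keys=True, default=str).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()[:12]
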