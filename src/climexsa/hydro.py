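"""Weekly climate series and the soil-moisture bucket model.

Growth and stress indices are computed on a 52-week year, so monthly
normals are first resampled to weeks: temperatures by cyclic linear
interpolation between month midpoints, precipitation by pro-rating each
month's total over the days of the week's midpoint month.  Soil moisture is
then a single-store bucket: weekly rainfall fills it, a temperature-scaled
evaporative demand empties it, and the store is expressed as a fraction of
bucket capacity so species moisture thresholds apply directly on the same
scale.  The annual cycle is iterated to a fixed point, which removes any
dependence on the initial storage value.

The weekly calendar is a fixed 52 x 7-day (364-day) year; normals are
climatological so no leap handling is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from ._calendar import DAYS_IN_MONTH, MONTH_MIDPOINTS

__all__ = ["BucketParameters", "monthly_to_weekly", "soil_moisture_series", "WEEK_MIDPOINTS"]

N_WEEKS = 52

#: Midpoint (in days, day 0 = Jan 1) of each of the 52 seven-day weeks.
WEEK_MIDPOINTS = 3.5 + 7.0 * np.arange(N_WEEKS)

# Month index (0-based) containing each week's midpoint day.
_MONTH_EDGES = np.cumsum(np.concatenate([[0], DAYS_IN_MONTH]))
_WEEK_MONTH = np.searchsorted(_MONTH_EDGES, WEEK_MIDPOINTS, side="right") - 1


@dataclass(frozen=True)
class BucketParameters:
    """Single-store soil water balance parameters.

    capacity : bucket capacity in mm (default 100).
    evap_coeff : evaporative demand per degree of above-zero weekly mean
        temperature, mm/degC/week.
    max_fraction : storage ceiling as a fraction of capacity; values above
        1 represent waterlogged states beyond field capacity.
    """

    capacity: float = 100.0
    evap_coeff: float = 1.0
    max_fraction: float = 2.5

    def __post_init__(self) -> None:
        if self.capacity <= 0:
            raise ValueError("bucket capacity must be positive")
        if self.evap_coeff < 0 or self.max_fraction <= 0:
            raise ValueError("evap_coeff must be >= 0 and max_fraction > 0")


def _interp_cyclic(monthly: np.ndarray) -> np.ndarray:
    """Interpolate ``(..., 12)`` month-midpoint values to week midpoints.

    Linear between successive month midpoints, cyclic over the 365-day year.
    """
    xp = np.concatenate([[MONTH_MIDPOINTS[-1] - 365.0], MONTH_MIDPOINTS, [MONTH_MIDPOINTS[0] + 365.0]])
    fp = np.concatenate([monthly[..., -1:], monthly, monthly[..., :1]], axis=-1)
    flat = fp.reshape(-1, 14)
    out = np.empty(flat.shape[:1] + (N_WEEKS,))
    for i in range(flat.shape[0]):
        out[i] = np.interp(WEEK_MIDPOINTS, xp, flat[i])
    return out.reshape(monthly.shape[:-1] + (N_WEEKS,))


def monthly_to_weekly(normals: xr.Dataset) -> xr.Dataset:
    """Resample monthly normals to a 52-week year.

    Temperatures (tmin, tmax and their mean tavg) are interpolated linearly
    between month midpoints; weekly precipitation is the midpoint month's
    total times 7 / days-in-month, which conserves the annual total to
    within a few tenths of a percent (the 364- vs 365-day mismatch).
    """
    for var in ("tmin", "tmax", "precip"):
        if var not in normals:
            raise ValueError(f"climate normals missing variable {var!r}")
    if normals.sizes.get("month") != 12:
        raise ValueError("climate normals must have exactly 12 months")

    tmin_m = normals["tmin"].transpose("lat", "lon", "month").values
    tmax_m = normals["tmax"].transpose("lat", "lon", "month").values
    precip_m = normals["precip"].transpose("lat", "lon", "month").values
    if np.any(tmin_m > tmax_m + 1e-9):
        raise ValueError("tmin exceeds tmax in input normals")

    tmin_w = _interp_cyclic(tmin_m)
    tmax_w = _interp_cyclic(tmax_m)
    tavg_w = 0.5 * (tmin_w + tmax_w)
    precip_w = precip_m[..., _WEEK_MONTH] * (7.0 / DAYS_IN_MONTH[_WEEK_MONTH])

    return xr.Dataset(
        {
            "tmin_w": (("lat", "lon", "week"), tmin_w),
            "tmax_w": (("lat", "lon", "week"), tmax_w),
            "tavg_w": (("lat", "lon", "week"), tavg_w),
            "precip_w": (("lat", "lon", "week"), precip_w),
        },
        coords={
            "lat": normals["lat"].values,
            "lon": normals["lon"].values,
            "week": np.arange(1, N_WEEKS + 1),
        },
        attrs=dict(normals.attrs),
    )


def soil_moisture_series(
    weekly: xr.Dataset,
    bucket: BucketParameters | None = None,
    tol: float = 1e-6,
    max_cycles: int = 20,
) -> xr.DataArray:
    """Converged weekly soil-moisture fraction of bucket capacity.

    Iterates ``sm_w = clamp(sm_{w-1} + (precip_w - E_w)/capacity, 0,
    max_fraction)`` with evaporative demand ``E_w = evap_coeff * max(0,
    tavg_w)`` around the annual cycle, starting from half capacity, until
    one further pass changes nothing (sup-norm below ``tol``) or
    ``max_cycles`` passes have run.
    """
    if bucket is None:
        bucket = BucketParameters()
    precip = weekly["precip_w"].transpose("lat", "lon", "week").values
    tavg = weekly["tavg_w"].transpose("lat", "lon", "week").values
    if np.any(precip < 0):
        raise ValueError("negative weekly precipitation")

    evap = bucket.evap_coeff * np.maximum(0.0, tavg)
    delta = (precip - evap) / bucket.capacity

    sm = np.full(precip.shape[:-1], 0.5)
    series = np.empty_like(precip)
    for _ in range(max_cycles):
        start = sm.copy()
        for w in range(N_WEEKS):
            sm = np.clip(sm + delta[..., w], 0.0, bucket.max_fraction)
            series[..., w] = sm
        if np.max(np.abs(sm - start)) < tol:
            break

    return xr.DataArray(
        series,
        dims=("lat", "lon", "week"),
        coords={
            "lat": weekly["lat"].values,
            "lon": weekly["lon"].values,
            "week": np.arange(1, N_WEEKS + 1),
        },
        name="soil_moisture",
        attrs={
            "capacity_mm": bucket.capacity,
            "evap_coeff": bucket.evap_coeff,
            "max_fraction": bucket.max_fraction,
        },
    )
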