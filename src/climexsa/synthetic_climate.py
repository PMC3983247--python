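"""Seeded synthetic climate normals and occurrence fixtures.

The generator emulates the structure of gridded long-term monthly climate
normals (12 monthly values per variable per cell: minimum and maximum
temperature, precipitation, 09:00 and 15:00 relative humidity) with simple,
controllable geography: a latitudinal temperature lapse, a seasonal sinusoid
whose phase inverts in the southern hemisphere, piecewise-latitudinal
precipitation bands, and humidity derived monotonically from the local
precipitation regime.  Everything is deterministic under a seed.

Controllability is the point: scenarios can be built in which exactly one
climatic axis (temperature or soil moisture) limits a species, which is what
the sensitivity-analysis tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from ._calendar import DAYS_IN_MONTH, MONTH_MIDPOINTS
from .grid import GridSpec
from .hydro import BucketParameters

__all__ = [
    "ClimateScenario",
    "generate_climate",
    "generate_occurrence_fixture",
    "temperature_limited_scenario",
    "temperature_limited_bucket",
    "moisture_limited_scenario",
    "moisture_limited_bucket",
    "DAYS_IN_MONTH",
]



@dataclass(frozen=True)
class ClimateScenario:
    """Parameters of the synthetic climate geography.

    Attributes
    ----------
    mean_temp_equator : float
        Annual-mean temperature at the equator, degC.
    lapse_per_degree : float
        Decrease of annual-mean temperature per degree of |latitude|,
        degC/degree. Non-negative.
    seasonal_amplitude : float
        Half-range of the annual temperature sinusoid, degC. The warm peak
        falls in July north of the equator and in January south of it.
    diurnal_half_range : float
        Half of the diurnal temperature range: tmin = tavg - h,
        tmax = tavg + h. Default 6 degC.
    precip_bands : tuple[tuple[float, float], ...]
        ``(latitude, annual_total_mm)`` anchors; a cell's annual
        precipitation is linearly interpolated between anchors on |latitude|
        (constant beyond the outermost anchors). Lets arid and humid zones
        be placed explicitly.
    precip_seasonality : float
        Fractional amplitude in [0, 1] of the seasonal precipitation
        sinusoid, peaking in winter (phase opposite to temperature).
    noise_amplitude : float
        Std-dev of a cell-wise Gaussian perturbation applied once to the
        annual-mean temperature (not per month), degC.
    precip_noise_fraction : float
        Coefficient of variation of a cell-wise multiplicative (lognormal,
        unit-mean) perturbation applied once to the annual precipitation
        total. Keeps the seasonal shape smooth while breaking the
        longitudinal degeneracy of the banded field.
    seed : int
        Seed for the noise fields; identical seed and scenario give
        bit-identical output.
    """

    mean_temp_equator: float = 28.0
    lapse_per_degree: float = 0.6
    seasonal_amplitude: float = 8.0
    diurnal_half_range: float = 6.0
    precip_bands: tuple[tuple[float, float], ...] = (
        (0.0, 1800.0),
        (20.0, 150.0),
        (45.0, 900.0),
        (70.0, 350.0),
    )
    precip_seasonality: float = 0.5
    noise_amplitude: float = 0.5
    precip_noise_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("seasonal_amplitude", "diurnal_half_range",
                     "precip_seasonality", "noise_amplitude",
                     "precip_noise_fraction", "lapse_per_degree"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.precip_seasonality > 1:
            raise ValueError("precip_seasonality must be <= 1")
        if any(total < 0 for _, total in self.precip_bands):
            raise ValueError("annual precipitation totals must be non-negative")


def generate_climate(spec: GridSpec, scenario: ClimateScenario) -> xr.Dataset:
    """Generate monthly climate normals on a grid.

    Returns an :class:`xarray.Dataset` with variables ``tmin``, ``tmax``
    (degC), ``precip`` (mm/month), ``rh09``, ``rh15`` (%), on dimensions
    ``(lat, lon, month)`` with ``month`` in 1..12.
    """
    lats = spec.lats
    lons = spec.lons
    months = np.arange(1, 13)

    abslat = np.abs(lats)
    annual_mean = scenario.mean_temp_equator - scenario.lapse_per_degree * abslat

    rng = np.random.default_rng(scenario.seed)
    noise = rng.normal(0.0, 1.0, size=(lats.size, lons.size)) * scenario.noise_amplitude
    annual_mean_2d = annual_mean[:, None] + noise

    # Warm peak at the July midpoint in the north; phase inverted in the south.
    phase = 2.0 * np.pi * (MONTH_MIDPOINTS - MONTH_MIDPOINTS[6]) / 365.0
    hemisphere = np.where(lats >= 0.0, 1.0, -1.0)
    seasonal = scenario.seasonal_amplitude * np.cos(phase)[None, None, :] * hemisphere[:, None, None]

    tavg = annual_mean_2d[:, :, None] + seasonal
    tmin = tavg - scenario.diurnal_half_range
    tmax = tavg + scenario.diurnal_half_range

    # Annual precipitation from latitudinal anchors, split into months with a
    # winter-peaked sinusoid (summer-peaked weights are the temperature
    # sinusoid's antiphase).
    band_lats = np.array([b[0] for b in scenario.precip_bands])
    band_tot = np.array([b[1] for b in scenario.precip_bands])
    order = np.argsort(band_lats)
    annual_precip = np.interp(abslat, band_lats[order], band_tot[order])
    if scenario.precip_noise_fraction > 0:
        sigma = np.sqrt(np.log1p(scenario.precip_noise_fraction**2))
        factor = np.exp(rng.normal(0.0, sigma, size=(lats.size, lons.size)) - sigma**2 / 2.0)
    else:
        factor = np.ones((lats.size, lons.size))
    annual_precip_2d = annual_precip[:, None] * factor

    weights = DAYS_IN_MONTH / 365.0 * (
        1.0 - scenario.precip_seasonality * np.cos(phase)[None, :] * hemisphere[:, None]
    )
    weights = weights / weights.sum(axis=1, keepdims=True)
    precip = annual_precip_2d[:, :, None] * weights[:, None, :]

    # Humidity rises monotonically with the annual precipitation band;
    # afternoon air is drier than morning air.
    wetness = np.clip(annual_precip / 2500.0, 0.0, 1.0)
    rh09 = 25.0 + 70.0 * wetness
    rh15 = np.clip(rh09 - 12.0, 0.0, 100.0)
    rh09_3d = np.broadcast_to(rh09[:, None, None], precip.shape).copy()
    rh15_3d = np.broadcast_to(rh15[:, None, None], precip.shape).copy()

    ds = xr.Dataset(
        {
            "tmin": (("lat", "lon", "month"), tmin),
            "tmax": (("lat", "lon", "month"), tmax),
            "precip": (("lat", "lon", "month"), precip),
            "rh09": (("lat", "lon", "month"), rh09_3d),
            "rh15": (("lat", "lon", "month"), rh15_3d),
        },
        coords={"lat": lats, "lon": lons, "month": months},
        attrs={
            "resolution": spec.resolution,
            "seed": scenario.seed,
            "title": "synthetic monthly climate normals",
        },
    )
    return ds


def generate_occurrence_fixture(
    n_total: int, n_missing_coords: int, spec: GridSpec, seed: int
) -> pd.DataFrame:
    """Generate an occurrence-record table with a controlled number of
    coordinate-free records.

    Returns a DataFrame with columns ``id, lat, lon, source``; records
    lacking coordinates have NaN lat/lon. Records with coordinates fall
    strictly inside the grid extent. Deterministic under ``seed``.
    """
    if n_total < 0 or n_missing_coords < 0:
        raise ValueError("record counts must be non-negative")
    if n_missing_coords > n_total:
        raise ValueError("n_missing_coords cannot exceed n_total")

    rng = np.random.default_rng(seed)
    lat = spec.lat_min + rng.random(n_total) * (spec.lat_max - spec.lat_min)
    lon = spec.lon_min + rng.random(n_total) * (spec.lon_max - spec.lon_min)
    missing = np.zeros(n_total, dtype=bool)
    if n_missing_coords:
        missing[rng.choice(n_total, size=n_missing_coords, replace=False)] = True
    lat[missing] = np.nan
    lon[missing] = np.nan
    sources = np.where(missing, "literature", "survey")
    return pd.DataFrame(
        {
            "id": [f"occ{1 + i:04d}" for i in range(n_total)],
            "lat": np.round(lat, 4),
            "lon": np.round(lon, 4),
            "source": sources,
        }
    )


def temperature_limited_scenario() -> ClimateScenario:
    """Control scenario in which only temperature limits growth.

    The annual-mean temperature runs from about 12.5 degC at the poleward
    edge to 39.4 degC near the equator, so the suitability contour can be
    moved by every temperature-response knot of a three-level screening
    design, from both the cold side (low-knot ramps) and the hot side (the
    upper-ramp tail of the hottest rows).  The diurnal range is zero and the
    seasonal cycle nearly flat, keeping weekly minima above every cold-stress
    threshold and maxima below every heat-stress threshold.  There is no
    rainfall; paired with :func:`temperature_limited_bucket` (zero
    evaporative demand) the soil store stays at half capacity, inside the
    moisture plateau of every candidate parameter set.
    """
    return ClimateScenario(
        mean_temp_equator=40.06,
        lapse_per_degree=0.565,
        seasonal_amplitude=0.3,
        diurnal_half_range=0.0,
        precip_bands=((0.0, 0.0),),
        precip_seasonality=0.0,
        noise_amplitude=0.0,
        precip_noise_fraction=0.0,
        seed=0,
    )


def temperature_limited_bucket() -> BucketParameters:
    """Bucket pairing for :func:`temperature_limited_scenario`: no rainfall
    and no evaporative demand pin the store at half capacity."""
    return BucketParameters(capacity=100.0, evap_coeff=0.0, max_fraction=2.5)


def moisture_limited_scenario() -> ClimateScenario:
    """Control scenario in which only soil moisture limits growth.

    Temperature is uniform at 28 degC with zero diurnal range: inside the
    optimal plateau of every candidate parameter set and clear of every
    cold/heat stress threshold, so the temperature axis is inert by
    construction.  Annual precipitation ramps with latitude through three
    regimes under a strongly seasonal (monsoonal) profile: a wide
    near-balance margin where the converged store peaks within the
    low-moisture knots, a buffer, and a humid zone whose cells fill to the
    free-drainage ceiling of :func:`moisture_limited_bucket` each wet season
    and dry out completely each dry season, so the high-moisture knots
    control whether those cells retain enough growing weeks to stay
    suitable.  Cell-wise precipitation noise breaks the longitudinal
    degeneracy of the banded field.
    """
    return ClimateScenario(
        mean_temp_equator=28.0,
        lapse_per_degree=0.0,
        seasonal_amplitude=0.5,
        diurnal_half_range=0.0,
        precip_bands=(
            (0.0, 870.0),
            (18.0, 950.0),
            (28.0, 1250.0),
            (36.0, 2600.0),
            (50.0, 4400.0),
        ),
        precip_seasonality=1.0,
        noise_amplitude=0.0,
        precip_noise_fraction=0.08,
        seed=0,
    )


def moisture_limited_bucket() -> BucketParameters:
    """Bucket pairing for :func:`moisture_limited_scenario`: a shallow
    (150 mm) free-draining store (ceiling 0.62 of capacity, i.e. excess
    drains off rather than waterlogging) under high evaporative demand, so
    wet-season spikes traverse the moisture response quickly and wet-stress
    exceedance stays marginal."""
    return BucketParameters(capacity=150.0, evap_coeff=1.2, max_fraction=0.62)
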