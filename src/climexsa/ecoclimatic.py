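"""The ecoclimatic suitability model.

Weekly growth is the product of two trapezoidal 0-1 responses: a
temperature index TI over the knots DV0 < DV1 <= DV2 < DV3 (limiting low,
lower optimal, upper optimal, limiting high temperature) evaluated on the
weekly mean temperature, and a moisture index MI over SM0 < SM1 <= SM2 <
SM3 evaluated on the weekly soil-moisture fraction.  The annual growth
index GI_A is the mean of the 52 weekly products.

Survival through the unfavourable season is handled by stress indices.
Each stress has a threshold and a weekly accumulation rate; the weekly
increment is rate x exceedance, and the accumulation grows superlinearly
with stress duration (the increment is weighted by the count of consecutive
stressed weeks), capped at 1, at which point the species cannot persist.
Cold stress accumulates below TTCS on the weekly minimum temperature, heat
stress above TTHS on the weekly maximum, wet stress above SMWS on soil
moisture.  No dry-stress parameters are defined for this species.

Growth and survival combine into the annual Ecoclimatic Index

    EI = 100 x GI_A x (1 - CS)(1 - HS)(1 - WS)   in [0, 100],

classified as unsuitable (EI = 0), marginal (0 < EI < 10), suitable
(10 <= EI < 20) or highly suitable (EI >= 20).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields, replace

import numpy as np
import xarray as xr

from .hydro import BucketParameters, monthly_to_weekly, soil_moisture_series

__all__ = [
    "SpeciesParameters",
    "DATE_PALM",
    "Category",
    "trapezoid_index",
    "temperature_index",
    "moisture_index",
    "growth_index_annual",
    "accumulate_stress",
    "ecoclimatic_index",
    "classify",
    "run_model",
]


class Category(enum.IntEnum):
    """Suitability categories, ordered. NODATA marks cells without climate."""

    NODATA = -1
    UNSUITABLE = 0
    MARGINAL = 1
    SUITABLE = 2
    HIGHLY_SUITABLE = 3

    @property
    def label(self) -> str:
        return self.name.lower()


@dataclass(frozen=True)
class SpeciesParameters:
    """The 14 species response parameters.

    Temperature knots DV0-DV3 (degC) and moisture knots SM0-SM3 (fraction
    of bucket capacity) define the growth trapezoids.  TTCS (degC) and THCS
    (/week, printed signed but applied by magnitude) govern cold stress;
    TTHS (degC) and THHS (/week) heat stress; SMWS (fraction) and HWS
    (/week) wet stress.
    """

    DV0: float
    DV1: float
    DV2: float
    DV3: float
    SM0: float
    SM1: float
    SM2: float
    SM3: float
    TTCS: float
    THCS: float
    TTHS: float
    THHS: float
    SMWS: float
    HWS: float

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for lo, hi, strict in (
            ("DV0", "DV1", True), ("DV1", "DV2", False), ("DV2", "DV3", True),
            ("SM0", "SM1", True), ("SM1", "SM2", False), ("SM2", "SM3", True),
        ):
            a, b = getattr(self, lo), getattr(self, hi)
            if (a >= b) if strict else (a > b):
                op = "<" if strict else "<="
                raise ValueError(f"parameter ordering violated: {lo}={a} must be {op} {hi}={b}")
        if self.THCS > 0:
            raise ValueError(f"THCS must be <= 0 (printed as a negative rate), got {self.THCS}")
        if self.THHS < 0 or self.HWS < 0:
            raise ValueError("THHS and HWS must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def with_values(self, **updates: float) -> "SpeciesParameters":
        return replace(self, **updates)


#: Baseline date palm (Phoenix dactylifera) parameter set.
DATE_PALM = SpeciesParameters(
    DV0=14.0, DV1=20.0, DV2=39.0, DV3=46.0,
    SM0=0.007, SM1=0.013, SM2=0.81, SM3=0.9,
    TTCS=4.0, THCS=-0.01, TTHS=46.0, THHS=0.9,
    SMWS=0.9, HWS=0.022,
)


def trapezoid_index(x, k0: float, k1: float, k2: float, k3: float):
    """Trapezoidal 0-1 response: 0 at/below k0 and at/above k3, 1 on
    [k1, k2], linear on the ramps."""
    if not (k0 < k1 <= k2 < k3):
        raise ValueError(f"trapezoid knots must satisfy k0 < k1 <= k2 < k3, got {(k0, k1, k2, k3)}")
    x = np.asarray(x, dtype=float)
    up = (x - k0) / (k1 - k0)
    down = (k3 - x) / (k3 - k2)
    return np.clip(np.minimum(up, down), 0.0, 1.0)


def temperature_index(tavg_w, p: SpeciesParameters):
    """Weekly temperature index TI over the DV knots."""
    return trapezoid_index(tavg_w, p.DV0, p.DV1, p.DV2, p.DV3)


def moisture_index(sm_w, p: SpeciesParameters):
    """Weekly moisture index MI over the SM knots."""
    return trapezoid_index(sm_w, p.SM0, p.SM1, p.SM2, p.SM3)


def growth_index_annual(ti_w, mi_w):
    """Annual growth index: mean over 52 weeks of the weekly TI x MI."""
    ti_w = np.asarray(ti_w, dtype=float)
    mi_w = np.asarray(mi_w, dtype=float)
    if ti_w.shape[-1] != 52 or mi_w.shape[-1] != 52:
        raise ValueError("weekly index series must have 52 weeks on the last axis")
    return np.mean(ti_w * mi_w, axis=-1)


def accumulate_stress(exceedance_w, rate: float):
    """Annual stress accumulation from weekly threshold exceedance.

    The weekly increment is ``|rate| * exceedance_w`` weighted by the number
    of consecutive stressed weeks up to and including the current one (the
    counter resets on any stress-free week), so sustained stress accumulates
    superlinearly.  The result is capped at 1.
    """
    ex = np.asarray(exceedance_w, dtype=float)
    if ex.shape[-1] != 52:
        raise ValueError("exceedance series must have 52 weeks on the last axis")
    if np.any(ex < 0):
        raise ValueError("exceedance must be non-negative")
    rate = abs(rate)
    total = np.zeros(ex.shape[:-1])
    streak = np.zeros(ex.shape[:-1])
    for w in range(52):
        stressed = ex[..., w] > 0
        streak = np.where(stressed, streak + 1, 0.0)
        total = total + rate * ex[..., w] * streak
    return np.minimum(total, 1.0)


def ecoclimatic_index(gi_a, cs, hs, ws):
    """Combine annual growth and stresses into EI on the 0-100 scale."""
    arrays = [np.asarray(a, dtype=float) for a in (gi_a, cs, hs, ws)]
    for a in arrays:
        if np.any((a < -1e-12) | (a > 1 + 1e-12)):
            raise ValueError("growth and stress indices must lie in [0, 1]")
    gi_a, cs, hs, ws = arrays
    return 100.0 * gi_a * (1.0 - cs) * (1.0 - hs) * (1.0 - ws)


def classify(ei):
    """Map EI values to categories (half-open upper-bound convention).

    EI = 0 unsuitable; 0 < EI < 10 marginal; 10 <= EI < 20 suitable;
    EI >= 20 highly suitable.  NaN maps to NODATA.
    """
    ei = np.asarray(ei, dtype=float)
    valid = ~np.isnan(ei)
    if np.any((ei[valid] < 0) | (ei[valid] > 100)):
        raise ValueError("EI outside [0, 100]")
    cat = np.full(ei.shape, int(Category.NODATA), dtype=np.int8)
    cat[valid & (ei == 0)] = Category.UNSUITABLE
    cat[valid & (ei > 0) & (ei < 10)] = Category.MARGINAL
    cat[valid & (ei >= 10) & (ei < 20)] = Category.SUITABLE
    cat[valid & (ei >= 20)] = Category.HIGHLY_SUITABLE
    return cat


def run_model(
    normals: xr.Dataset,
    p: SpeciesParameters,
    bucket: BucketParameters | None = None,
    weekly: xr.Dataset | None = None,
    soil_moisture: xr.DataArray | None = None,
) -> xr.Dataset:
    """Run the full model on gridded normals.

    Composes weekly resampling, the soil-moisture bucket, growth and stress
    indices, EI and classification.  ``weekly`` and ``soil_moisture`` may be
    supplied to reuse climate-only precomputations (they do not depend on
    the species parameters).  Cells with missing climate become NODATA.

    Returns a Dataset with ``EI``, ``category``, ``GI_A``, ``CS``, ``HS``,
    ``WS`` on (lat, lon).
    """
    if weekly is None:
        weekly = monthly_to_weekly(normals)
    if soil_moisture is None:
        soil_moisture = soil_moisture_series(weekly, bucket)

    tavg = weekly["tavg_w"].transpose("lat", "lon", "week").values
    tmin = weekly["tmin_w"].transpose("lat", "lon", "week").values
    tmax = weekly["tmax_w"].transpose("lat", "lon", "week").values
    sm = soil_moisture.transpose("lat", "lon", "week").values

    missing = np.isnan(tavg).any(axis=-1) | np.isnan(sm).any(axis=-1)

    ti = temperature_index(np.nan_to_num(tavg), p)
    mi = moisture_index(np.nan_to_num(sm), p)
    gi_a = growth_index_annual(ti, mi)

    cs = accumulate_stress(np.maximum(0.0, p.TTCS - np.nan_to_num(tmin)), p.THCS)
    hs = accumulate_stress(np.maximum(0.0, np.nan_to_num(tmax) - p.TTHS), p.THHS)
    ws = accumulate_stress(np.maximum(0.0, np.nan_to_num(sm) - p.SMWS), p.HWS)

    ei = ecoclimatic_index(gi_a, cs, hs, ws)
    ei[missing] = np.nan
    cat = classify(ei)

    coords = {"lat": weekly["lat"].values, "lon": weekly["lon"].values}
    return xr.Dataset(
        {
            "EI": (("lat", "lon"), ei),
            "category": (("lat", "lon"), cat),
            "GI_A": (("lat", "lon"), np.where(missing, np.nan, gi_a)),
            "CS": (("lat", "lon"), np.where(missing, np.nan, cs)),
            "HS": (("lat", "lon"), np.where(missing, np.nan, hs)),
            "WS": (("lat", "lon"), np.where(missing, np.nan, ws)),
        },
        coords=coords,
        attrs={"resolution": normals.attrs.get("resolution", float("nan"))},
    )
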