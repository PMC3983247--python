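"""Regular geographic grid specification.

Cells are axis-aligned lat/lon boxes of uniform angular resolution; the
coordinate arrays hold cell *centers* (latitude positive north, longitude
positive east, WGS84 convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec"]


@dataclass(frozen=True)
class GridSpec:
    """Extent and resolution of a regular lat/lon grid.

    Parameters
    ----------
    lat_min, lat_max, lon_min, lon_max : float
        Outer edges of the grid, degrees.
    resolution : float
        Cell size in degrees (same along both axes). Default 0.5, the
        resolution of typical global climate-normal grids.
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    resolution: float = 0.5

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        if not self.lat_max > self.lat_min:
            raise ValueError("lat_max must exceed lat_min")
        if not self.lon_max > self.lon_min:
            raise ValueError("lon_max must exceed lon_min")
        if self.nlat < 1 or self.nlon < 1:
            raise ValueError("grid extent smaller than one cell")
        if self.lat_min < -90 or self.lat_max > 90:
            raise ValueError("latitude extent outside [-90, 90]")

    @property
    def nlat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.resolution))

    @property
    def nlon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.resolution))

    @property
    def lats(self) -> np.ndarray:
        """Cell-center latitudes, south to north."""
        return self.lat_min + self.resolution * (np.arange(self.nlat) + 0.5)

    @property
    def lons(self) -> np.ndarray:
        """Cell-center longitudes, west to east."""
        return self.lon_min + self.resolution * (np.arange(self.nlon) + 0.5)

    def cell_index(self, lat: float, lon: float) -> tuple[int, int] | None:
        """Indices of the cell containing a point, or None if outside.

        Cells are half-open ``[west, east) x [south, north)``: a point on a
        cell's western or southern edge belongs to that cell; a point on the
        grid's outer eastern/northern edge is outside.
        """
        i = int(np.floor((lat - self.lat_min) / self.resolution))
        j = int(np.floor((lon - self.lon_min) / self.resolution))
        if 0 <= i < self.nlat and 0 <= j < self.nlon:
            return i, j
        return None
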