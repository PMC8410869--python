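"""Regular lon/lat grids shared by every gridded field in the package.

All climatologies, suitability cubes and change fields live on a single
:class:`GridSpec` — a regular grid of square cells with centers at
``min + cell_size/2 + k*cell_size``.  Cell membership is half-open
``[west, east) x [south, north)``; longitudes are normalised to
``[-180, 180)``.  Points lying exactly on the northern grid edge are
assigned to the last row so that the pole is not silently lost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

__all__ = ["GridSpec"]


@dataclass(frozen=True)
class GridSpec:
    """A regular monthly lon/lat grid.

    Parameters
    ----------
    lon_min, lon_max, lat_min, lat_max : float
        Grid bounds in degrees.
    cell_size : float
        Cell edge length in degrees; must divide both spans evenly.
    months : int
        Number of months resolved (12 for a climatological year).
    """

    lon_min: float = -180.0
    lon_max: float = 180.0
    lat_min: float = -90.0
    lat_max: float = 90.0
    cell_size: float = 10.0
    months: int = 12

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not (1 <= self.months <= 12):
            raise ValueError("months must be in 1..12")
        for span, name in (
            (self.lon_max - self.lon_min, "longitude"),
            (self.lat_max - self.lat_min, "latitude"),
        ):
            if span <= 0:
                raise ValueError(f"empty {name} span")
            n = span / self.cell_size
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"cell_size {self.cell_size} does not divide the {name} span {span}"
                )

    # ------------------------------------------------------------------ sizes
    @property
    def n_lon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.cell_size))

    @property
    def n_lat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.cell_size))

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + self.cell_size * (0.5 + np.arange(self.n_lon))

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + self.cell_size * (0.5 + np.arange(self.n_lat))

    @property
    def month_values(self) -> np.ndarray:
        return np.arange(1, self.months + 1)

    # ------------------------------------------------------------- membership
    @staticmethod
    def wrap_lon(lon):
        """Normalise longitudes to [-180, 180)."""
        return ((np.asarray(lon, dtype=float) + 180.0) % 360.0) - 180.0

    def cell_of(self, lon, lat):
        """Return integer cell indices ``(ilat, ilon)`` for coordinates.

        Longitudes are wrapped; latitudes exactly on the northern bound
        fall into the top row.  Out-of-bounds latitudes yield -1.
        """
        lon = self.wrap_lon(lon)
        lat = np.asarray(lat, dtype=float)
        ilon = np.floor((lon - self.lon_min) / self.cell_size).astype(int)
        # wrap longitude index for global grids; clamp otherwise
        if abs((self.lon_max - self.lon_min) - 360.0) < 1e-9:
            ilon = ilon % self.n_lon
        ilat = np.floor((lat - self.lat_min) / self.cell_size).astype(int)
        top = np.isclose(lat, self.lat_max)
        ilat = np.where(top, self.n_lat - 1, ilat)
        oob = (lat < self.lat_min) | (lat > self.lat_max) | (ilon < 0) | (ilon >= self.n_lon)
        ilat = np.where(oob, -1, ilat)
        ilon = np.where(oob, -1, ilon)
        return ilat, ilon

    # ------------------------------------------------------------------ xarray
    def coords(self, monthly: bool = True) -> dict:
        c = {"lat": self.lat_centers, "lon": self.lon_centers}
        if monthly:
            c = {"month": self.month_values, **c}
        return c

    def empty_field(self, monthly: bool = True, fill=np.nan) -> xr.DataArray:
        coords = self.coords(monthly)
        shape = tuple(len(v) for v in coords.values())
        return xr.DataArray(np.full(shape, fill, dtype=float), coords=coords, dims=list(coords))

    def same_grid(self, other: "GridSpec") -> bool:
        return self == other

    @property
    def cell_area_weights(self) -> xr.DataArray:
        """cos(latitude) area weights on cell centers (unnormalised)."""
        w = np.cos(np.deg2rad(self.lat_centers))
        return xr.DataArray(w, coords={"lat": self.lat_centers}, dims=["lat"])
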