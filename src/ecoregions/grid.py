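"""Gridded monthly fields and time-slot arithmetic.

The central container is :class:`GriddedField`: a (time, lat, lon) array of
monthly values on a regular latitude-longitude grid with an ocean/land mask.
Raw SST, anomalies, velocity components and kinetic energy all use it.  Land
cells hold NaN and are excluded from every statistic downstream.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

__all__ = ["GriddedField", "TimeSlot", "read_gridded"]


@dataclass
class GriddedField:
    """A (time x lat x lon) monthly field with coordinates and an ocean mask.

    Parameters
    ----------
    values : ndarray, shape (T, nlat, nlon)
        Field values; NaN on land cells.
    time : pandas.DatetimeIndex
        Strictly increasing, monthly timestamps.
    lat, lon : ndarray
        Coordinate vectors in degrees.
    mask : ndarray of bool, shape (nlat, nlon)
        True for ocean cells.
    units : str
    """

    values: np.ndarray
    time: pd.DatetimeIndex
    lat: np.ndarray
    lon: np.ndarray
    mask: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time = pd.DatetimeIndex(self.time)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("values must be (time, lat, lon)")
        if self.values.shape != (len(self.time), len(self.lat), len(self.lon)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"(time={len(self.time)}, lat={len(self.lat)}, lon={len(self.lon)})"
            )
        if self.mask.shape != (len(self.lat), len(self.lon)):
            raise ValueError("mask shape must be (nlat, nlon)")
        periods = self.time.to_period("M").astype("int64")
        if len(periods) > 1 and not np.all(np.diff(periods) == 1):
            raise ValueError("time must be strictly increasing and monthly")

    # -- basic geometry -------------------------------------------------
    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    @property
    def nlat(self) -> int:
        return self.values.shape[1]

    @property
    def nlon(self) -> int:
        return self.values.shape[2]

    @property
    def years(self) -> np.ndarray:
        return self.time.year.to_numpy()

    @property
    def months(self) -> np.ndarray:
        """Calendar month (1..12) of each time step."""
        return self.time.month.to_numpy()

    def ocean_values(self) -> np.ndarray:
        """Values restricted to ocean cells, shape (T, n_ocean)."""
        return self.values[:, self.mask]

    def with_values(self, values: np.ndarray, units: str | None = None) -> "GriddedField":
        """Copy of this field with new values on the same grid."""
        return replace(
            self, values=np.asarray(values, dtype=float),
            units=self.units if units is None else units,
        )

    def congruent(self, other: "GriddedField") -> bool:
        """True if the two fields share grid, mask and time axis."""
        return (
            self.values.shape == other.values.shape
            and np.array_equal(self.lat, other.lat)
            and np.array_equal(self.lon, other.lon)
            and np.array_equal(self.mask, other.mask)
            and self.time.equals(other.time)
        )

    # -- I/O -------------------------------------------------------------
    def to_dataset(self, name: str = "field") -> xr.Dataset:
        da = xr.DataArray(
            self.values,
            dims=("time", "lat", "lon"),
            coords={"time": self.time, "lat": self.lat, "lon": self.lon},
            name=name,
            attrs={"units": self.units},
        )
        mask = xr.DataArray(
            self.mask.astype(np.int8), dims=("lat", "lon"), name="mask",
            attrs={"long_name": "ocean mask (1=ocean, 0=land)"},
        )
        return xr.Dataset({name: da, "mask": mask})

    def to_netcdf(self, path, name: str = "field") -> None:
        # scipy backend -> NetCDF-3 classic, no compiled netCDF library needed
        self.to_dataset(name).to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset, name: str = "field") -> "GriddedField":
        da = ds[name]
        return cls(
            values=da.values,
            time=pd.DatetimeIndex(ds["time"].values),
            lat=ds["lat"].values,
            lon=ds["lon"].values,
            mask=ds["mask"].values.astype(bool),
            units=da.attrs.get("units", ""),
        )


def read_gridded(path, name: str = "field") -> GriddedField:
    with xr.open_dataset(path, engine="scipy") as ds:
        return GriddedField.from_dataset(ds.load(), name)


@dataclass(frozen=True)
class TimeSlot:
    """A [yr_ini, yr_ini + delta) analysis window, in whole years.

    The printed form is inclusive on both ends ("1987-1993" for yr_ini=1987,
    delta=7); internally the window is half-open on the month axis and spans
    exactly 12*delta months.
    """

    yr_ini: int
    delta: int

    def __post_init__(self) -> None:
        if self.delta < 1:
            raise ValueError("delta must be >= 1 year")

    @property
    def yr_end(self) -> int:
        """Exclusive end year: yr_ini + delta."""
        return self.yr_ini + self.delta

    @property
    def n_months(self) -> int:
        return 12 * self.delta

    def contains_years(self, years: np.ndarray) -> np.ndarray:
        """Boolean selector over a vector of calendar years."""
        years = np.asarray(years)
        return (years >= self.yr_ini) & (years < self.yr_end)

    def overlap_years(self, start: int, stop: int) -> int:
        """Number of whole years shared with the half-open period [start, stop)."""
        return max(0, min(self.yr_end, stop) - max(self.yr_ini, start))

    def __str__(self) -> str:
        return f"{self.yr_ini}-{self.yr_end - 1}"
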