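"""Gridded-variable ("climate cube") conventions and NetCDF I/O.

A climate cube is an :class:`xarray.DataArray` with dimensions
``(year, lat, lon)`` (or ``(time, lat, lon)`` for monthly data), cell-center
coordinates in degrees north/east, a non-empty ``units`` attribute, and NaN
marking masked cells.  Files are written with the SciPy NetCDF3 backend so no
compiled NetCDF library is required.
"""

from __future__ import annotations

import os
from collections.abc import Iterable

import numpy as np
import pandas as pd
import xarray as xr

NETCDF_ENGINE = "scipy"


def make_cube(
    values: np.ndarray,
    years: Iterable[int],
    lats: Iterable[float],
    lons: Iterable[float],
    name: str,
    units: str,
) -> xr.DataArray:
    """Assemble a (year, lat, lon) cube and validate its coordinates."""
    da = xr.DataArray(
        np.asarray(values, dtype=float),
        dims=("year", "lat", "lon"),
        coords={
            "year": np.asarray(list(years), dtype=int),
            "lat": np.asarray(list(lats), dtype=float),
            "lon": np.asarray(list(lons), dtype=float),
        },
        name=name,
        attrs={"units": units},
    )
    validate_cube(da)
    return da


def validate_cube(da: xr.DataArray) -> None:
    """Check cube invariants; raise ``ValueError`` on violation."""
    for dim in ("lat", "lon"):
        if dim not in da.dims:
            raise ValueError(f"cube {da.name!r} lacks dimension {dim!r}")
        coord = da[dim].values
        diffs = np.diff(coord)
        if coord.size > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError(f"coordinate {dim!r} is not strictly monotone")
    if not da.attrs.get("units"):
        raise ValueError(f"cube {da.name!r} has no units attribute")


def normalize_lon(lon: np.ndarray) -> np.ndarray:
    """Normalize longitudes to [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


def save_cube(da: xr.DataArray, path: str | os.PathLike) -> None:
    da.to_netcdf(path, engine=NETCDF_ENGINE)


def save_dataset(ds: xr.Dataset, path: str | os.PathLike) -> None:
    ds.to_netcdf(path, engine=NETCDF_ENGINE)


def load_cube(path: str | os.PathLike, name: str | None = None) -> xr.DataArray:
    """Read one variable from a NetCDF file (the only variable if unnamed)."""
    with xr.open_dataset(path, engine=NETCDF_ENGINE) as ds:
        if name is None:
            data_vars = list(ds.data_vars)
            if len(data_vars) != 1:
                raise ValueError(
                    f"{path} holds {data_vars}; specify which variable to load"
                )
            name = data_vars[0]
        if name not in ds:
            raise KeyError(f"variable {name!r} not found in {path}")
        return ds[name].load()


def load_dataset(path: str | os.PathLike) -> xr.Dataset:
    with xr.open_dataset(path, engine=NETCDF_ENGINE) as ds:
        return ds.load()


def load_co2_series(path: str | os.PathLike) -> pd.Series:
    """Read a scalar CO2 record from a two-column CSV (year, ppm)."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "year" not in cols or "ppm" not in cols:
        raise ValueError(f"{path} must have columns 'year' and 'ppm'")
    series = pd.Series(
        df[cols["ppm"]].to_numpy(dtype=float),
        index=df[cols["year"]].to_numpy(dtype=int),
        name="co2",
    )
    series.index.name = "year"
    return series
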