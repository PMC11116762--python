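"""Grid handling: nearest-neighbor regridding, area weighting, trend maps,
and area-fraction summaries.

Area weights are proportional to cos(latitude) of the cell center (a
cell-count option is available for comparison).  Per-pixel trends use the
same closed-form OLS slope / t-test engine for any variable; a Mann-Kendall
alternative is provided but off by default.
"""

from __future__ import annotations

import numpy as np
import xarray as xr
from scipy import stats


def regrid_nearest(
    da: xr.DataArray,
    target_lat: np.ndarray,
    target_lon: np.ndarray,
) -> xr.DataArray:
    """Nearest-neighbor regrid onto (target_lat, target_lon) cell centers.

    Distance is the plain Euclidean metric in degrees, separable per axis;
    ties break toward the lower source index.  Masked (NaN) source cells
    propagate to every target cell that maps to them.  Identical grids give
    the identity (so the operation is idempotent).
    """
    target_lat = np.asarray(target_lat, dtype=float)
    target_lon = np.asarray(target_lon, dtype=float)
    src_lat = da["lat"].values
    src_lon = da["lon"].values
    _check_overlap(src_lat, target_lat, "lat")
    _check_overlap(src_lon, target_lon, "lon")
    ilat = _nearest_index(src_lat, target_lat)
    ilon = _nearest_index(src_lon, target_lon)
    out = da.isel(lat=xr.DataArray(ilat, dims="lat"), lon=xr.DataArray(ilon, dims="lon"))
    out = out.assign_coords(lat=target_lat, lon=target_lon)
    out.attrs = dict(da.attrs)
    return out


def _nearest_index(src: np.ndarray, target: np.ndarray) -> np.ndarray:
    # argmin returns the first (lowest-index) minimizer, the required tie-break
    dist = np.abs(target[:, None] - src[None, :])
    return dist.argmin(axis=1)


def _check_overlap(src: np.ndarray, target: np.ndarray, name: str) -> None:
    if target.min() > src.max() + 90 or target.max() < src.min() - 90:
        raise ValueError(f"source and target {name} ranges are disjoint")


def area_weights(lat: np.ndarray) -> np.ndarray:
    """Weights proportional to cos(latitude in degrees), clipped at 0."""
    return np.clip(np.cos(np.deg2rad(np.asarray(lat, dtype=float))), 0.0, None)


def area_weighted_mean(
    field: xr.DataArray,
    region_mask: xr.DataArray | None = None,
    weighting: str = "area",
):
    """cos(lat)-weighted mean of a field over unmasked cells.

    Works on a 2-D (lat, lon) field or any cube with extra leading dims (the
    mean is taken over lat/lon, returning a series).  ``weighting="count"``
    gives the plain unweighted mean.  Raises on an empty region.
    """
    if weighting not in ("area", "count"):
        raise ValueError(f"unknown weighting {weighting!r}")
    data = field
    if region_mask is not None:
        data = data.where(region_mask > 0)
    if weighting == "area":
        w = xr.DataArray(area_weights(data["lat"].values), dims="lat",
                         coords={"lat": data["lat"].values})
    else:
        w = xr.ones_like(data["lat"], dtype=float)
    valid = data.notnull()
    if int(valid.sum()) == 0:
        raise ValueError("region contains no unmasked cells")
    wsum = (data * w).sum(dim=("lat", "lon"), skipna=True)
    norm = (valid * w).sum(dim=("lat", "lon"))
    out = wsum / norm
    return float(out) if out.ndim == 0 else out


def pixel_trend_map(
    cube: xr.DataArray,
    dim: str | None = None,
    alpha: float = 0.05,
    method: str = "ols",
    min_points: int = 3,
) -> xr.Dataset:
    """Per-pixel linear trend of a (time, lat, lon) cube.

    Returns a Dataset with ``slope`` (input units per year), ``p_value``,
    ``significant`` (p < alpha) and ``n`` layers.  ``method="ols"`` uses the
    closed-form slope with a two-sided t-test (df = n - 2, no autocorrelation
    correction); ``method="mannkendall"`` substitutes the Mann-Kendall S test
    for the p-value while keeping the OLS slope.  Pixels with fewer than
    ``min_points`` valid time steps are masked.
    """
    if method not in ("ols", "mannkendall"):
        raise ValueError(f"unknown trend method {method!r}")
    if dim is None:
        dim = next(d for d in ("year", "window_center", "time") if d in cube.dims)
    cube = cube.transpose(dim, "lat", "lon")
    t = np.asarray(cube[dim].values, dtype=float)
    y = cube.values  # (nt, nlat, nlon)
    finite = np.isfinite(y)
    n = finite.sum(axis=0)

    ym = np.where(finite, y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tbar = (finite * t[:, None, None]).sum(axis=0) / n
        ybar = ym.sum(axis=0) / n
        tdev = np.where(finite, t[:, None, None] - tbar, 0.0)
        ydev = np.where(finite, y - ybar, 0.0)
        sxx = (tdev**2).sum(axis=0)
        sxy = (tdev * ydev).sum(axis=0)
        slope = sxy / sxx
        resid = np.where(finite, ydev - slope * tdev, 0.0)
        dof = n - 2
        sigma2 = (resid**2).sum(axis=0) / np.where(dof > 0, dof, 1)
        se = np.sqrt(sigma2 / sxx)
        tval = slope / se
    p = np.where(se > 0, 2.0 * stats.t.sf(np.abs(tval), np.where(dof > 0, dof, 1)), 0.0)
    p = np.where(slope == 0, np.where(se > 0, p, 1.0), p)

    if method == "mannkendall":
        p = _mann_kendall_p(y, finite, n)

    bad = (n < min_points) | (sxx <= 0)
    slope = np.where(bad, np.nan, slope)
    p = np.where(bad, np.nan, p)
    ds = xr.Dataset(
        {
            "slope": (("lat", "lon"), slope),
            "p_value": (("lat", "lon"), p),
            "significant": (("lat", "lon"), (p < alpha) & ~bad),
            "n": (("lat", "lon"), n.astype(int)),
        },
        coords={"lat": cube["lat"].values, "lon": cube["lon"].values},
    )
    unit = cube.attrs.get("units", "")
    ds["slope"].attrs["units"] = f"{unit} per year".strip()
    ds.attrs["alpha"] = alpha
    ds.attrs["method"] = method
    return ds


def _mann_kendall_p(y: np.ndarray, finite: np.ndarray, n: np.ndarray) -> np.ndarray:
    nt, nlat, nlon = y.shape
    p = np.full((nlat, nlon), np.nan)
    for i in range(nlat):
        for j in range(nlon):
            yy = y[finite[:, i, j], i, j]
            m = yy.size
            if m < 3:
                continue
            s = np.sum(np.sign(yy[None, :] - yy[:, None])[np.triu_indices(m, 1)])
            var = m * (m - 1) * (2 * m + 5) / 18.0
            z = (s - np.sign(s)) / np.sqrt(var) if var > 0 else 0.0
            p[i, j] = 2.0 * stats.norm.sf(abs(z))
    return p


def fraction_with_trend(
    trend: xr.Dataset,
    sign: str = "negative",
    significant_only: bool = False,
    weighting: str = "area",
) -> float:
    """Area-weighted fraction of unmasked cells whose slope has ``sign``.

    ``sign`` is ``"negative"`` or ``"positive"``; with ``significant_only``
    the count is restricted to cells with p below the trend field's alpha.
    Fractions of opposite signs plus the zero-slope fraction sum to 1 over
    the unmasked region.
    """
    if sign not in ("negative", "positive", "zero"):
        raise ValueError(f"unknown sign {sign!r}")
    slope = trend["slope"]
    valid = slope.notnull()
    if int(valid.sum()) == 0:
        raise ValueError("trend field has no unmasked cells")
    if sign == "negative":
        sel = slope < 0
    elif sign == "positive":
        sel = slope > 0
    else:
        sel = valid & (slope == 0)
    if significant_only:
        sel = sel & (trend["significant"] > 0)
    if weighting == "area":
        w = xr.DataArray(area_weights(slope["lat"].values), dims="lat",
                         coords={"lat": slope["lat"].values})
    elif weighting == "count":
        w = xr.ones_like(slope["lat"], dtype=float)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    num = float((sel * w).sum())
    den = float((valid * w).sum())
    return num / den


def latitude_band_mask(
    template: xr.DataArray,
    lat_min: float = 30.0,
    lat_max: float = 90.0,
) -> xr.DataArray:
    """0/1 region mask selecting cells with lat_min <= lat <= lat_max."""
    lat = template["lat"]
    mask = ((lat >= lat_min) & (lat <= lat_max)).astype(int)
    return mask.broadcast_like(template.isel({d: 0 for d in template.dims if d not in ("lat", "lon")}, drop=True)).rename("region_mask")
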