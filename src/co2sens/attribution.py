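"""Driver attribution of the windowed beta series.

Per pixel, the windowed beta series is regressed on driver series averaged
over the same moving windows (VPD; water availability = precipitation minus
ET; N deposition; P deposition — or soil N replacing the depositions in
future mode):

    beta = a1*VPD + a2*Wa + a3*Nit + a4*Pho + intercept + eps

Each driver's standardized coefficient is |a_X| * std(X) / std(beta); note the
denominator follows the textual definition (std of the beta series), and the
absolute value makes the relative contributions

    R_X = Stc_X / sum(Stc)

non-negative and summing to one.  Signed coefficients are preserved for
inspection.  A partial-correlation cross-check (residual-on-residual) is
reported separately.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from co2sens.beta import ols, window_starts
from co2sens.spatial import area_weights

HISTORICAL_DRIVERS = ("vpd", "wa", "nit", "pho")
FUTURE_DRIVERS = ("vpd", "wa", "soil_n")


def window_means(
    series: np.ndarray, window_len: int = 15, stride: int = 1
) -> np.ndarray:
    """Mean of each sliding window, aligned with the beta window axis."""
    series = np.asarray(series, dtype=float)
    starts = window_starts(series.shape[0], window_len, stride)
    return np.stack([series[s : s + window_len].mean(axis=0) for s in starts])


def fit_driver_regression(
    beta_series: np.ndarray, drivers: dict[str, np.ndarray]
) -> dict[str, float] | None:
    """OLS of the beta series on windowed drivers (intercept included).

    Returns ``{driver: coefficient, "intercept": value}`` or None when the
    pixel must be masked: fewer windows than coefficients + 1, or a
    rank-deficient design.
    """
    y = np.asarray(beta_series, dtype=float)
    names = list(drivers)
    X = np.column_stack([np.asarray(drivers[k], dtype=float) for k in names])
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[keep], X[keep]
    k = len(names)
    if y.size < k + 2:
        return None
    design = np.column_stack([X, np.ones(y.size)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        return None
    fit = ols(design, y)
    out = {name: float(c) for name, c in zip(names, fit.coefs[:-1])}
    out["intercept"] = float(fit.coefs[-1])
    return out


def standardized_coefficients(
    coefficients: dict[str, float],
    drivers: dict[str, np.ndarray],
    beta_series: np.ndarray,
) -> dict[str, float] | None:
    """``Stc_X = |a_X| * std(X) / std(beta)`` per driver; None if std(beta)=0.

    A constant driver (std = 0) gets Stc = 0.  Stc is invariant to driver
    unit changes: rescaling X by c rescales a_X by 1/c and std(X) by c.
    """
    beta_series = np.asarray(beta_series, dtype=float)
    sd_beta = float(np.nanstd(beta_series))
    if not np.isfinite(sd_beta) or sd_beta == 0:
        return None
    return {
        name: abs(coefficients[name]) * float(np.nanstd(np.asarray(x, dtype=float))) / sd_beta
        for name, x in drivers.items()
    }


def relative_contributions(stc: dict[str, float]) -> dict[str, float] | None:
    """Normalize standardized coefficients to shares summing to 1.

    Returns None (pixel masked) when every Stc is zero.
    """
    total = sum(stc.values())
    if total <= 0:
        return None
    return {name: v / total for name, v in stc.items()}


def partial_correlation(
    beta_series: np.ndarray, drivers: dict[str, np.ndarray]
) -> dict[str, float] | None:
    """Partial correlation of beta with each driver, controlling for the rest.

    Residual-on-residual method: regress beta and the target driver on all
    other drivers (plus intercept), then correlate the residuals.  Returns
    None when a control regression is singular or there are too few windows.
    """
    y = np.asarray(beta_series, dtype=float)
    names = list(drivers)
    X = np.column_stack([np.asarray(drivers[k], dtype=float) for k in names])
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[keep], X[keep]
    if y.size < len(names) + 2 or y.size < 5:
        return None
    out = {}
    for idx, name in enumerate(names):
        controls = np.column_stack(
            [np.delete(X, idx, axis=1), np.ones(y.size)]
        )
        if np.linalg.matrix_rank(controls) < controls.shape[1]:
            return None
        ry = y - controls @ np.linalg.lstsq(controls, y, rcond=None)[0]
        rx = X[:, idx] - controls @ np.linalg.lstsq(controls, X[:, idx], rcond=None)[0]
        ry_ss, rx_ss = float(ry @ ry), float(rx @ rx)
        # residuals at floating-point-noise level count as exactly zero
        if rx_ss <= 1e-24 * float(X[:, idx] @ X[:, idx]):
            return None  # driver collinear with the controls
        if ry_ss <= 1e-24 * max(float(y @ y), 1e-300):
            out[name] = 0.0  # beta fully explained by the controls
            continue
        out[name] = float(ry @ rx) / np.sqrt(ry_ss * rx_ss)
    return out


def partial_correlation_shares(
    beta_series: np.ndarray, drivers: dict[str, np.ndarray]
) -> dict[str, float] | None:
    """Shares = |partial r| normalized across drivers (cross-check scheme)."""
    r = partial_correlation(beta_series, drivers)
    if r is None:
        return None
    total = sum(abs(v) for v in r.values())
    if total == 0:
        return None
    return {name: abs(v) / total for name, v in r.items()}


def attribute_pixel(
    beta_series: np.ndarray, drivers: dict[str, np.ndarray]
) -> dict[str, float] | None:
    """Full per-pixel attribution: coefficients, Stc and R values, or None."""
    coefs = fit_driver_regression(beta_series, drivers)
    if coefs is None:
        return None
    stc = standardized_coefficients(coefs, drivers, beta_series)
    if stc is None:
        return None
    shares = relative_contributions(stc)
    if shares is None:
        return None
    out = {f"coef_{k}": v for k, v in coefs.items()}
    out.update({f"stc_{k}": v for k, v in stc.items()})
    out.update({f"r_{k}": v for k, v in shares.items()})
    return out


def attribute_cube(
    beta_cube: xr.DataArray,
    driver_cubes: dict[str, xr.DataArray],
    window_len: int = 15,
    stride: int = 1,
) -> xr.Dataset:
    """Grid-level attribution of the windowed beta field.

    ``beta_cube`` has dims (window_center, lat, lon); each driver cube has
    dims (year, lat, lon) on the matching annual axis and is averaged over
    the same windows before the per-pixel regression.  Pixels where the
    regression or normalization is undefined come back NaN.
    """
    names = list(driver_cubes)
    beta_v = beta_cube.transpose("window_center", "lat", "lon").values
    nlat, nlon = beta_cube.sizes["lat"], beta_cube.sizes["lon"]
    windowed = {
        k: window_means(
            v.transpose("year", "lat", "lon").values, window_len, stride
        )
        for k, v in driver_cubes.items()
    }
    for k, w in windowed.items():
        if w.shape[0] != beta_v.shape[0]:
            raise ValueError(
                f"driver {k!r} yields {w.shape[0]} windows but beta has {beta_v.shape[0]}"
            )
    keys = [f"coef_{k}" for k in names + ["intercept"]]
    keys += [f"stc_{k}" for k in names] + [f"r_{k}" for k in names]
    fields = {k: np.full((nlat, nlon), np.nan) for k in keys}
    for i in range(nlat):
        for j in range(nlon):
            res = attribute_pixel(
                beta_v[:, i, j], {k: windowed[k][:, i, j] for k in names}
            )
            if res is None:
                continue
            for k, v in res.items():
                fields[k][i, j] = v
    ds = xr.Dataset(
        {k: (("lat", "lon"), v) for k, v in fields.items()},
        coords={"lat": beta_cube["lat"].values, "lon": beta_cube["lon"].values},
    )
    ds.attrs["drivers"] = ",".join(names)
    return ds


def regional_contribution_summary(
    contributions: xr.Dataset,
    region_mask: xr.DataArray | None = None,
    weighting: str = "area",
    pool_nutrients: bool = False,
) -> pd.DataFrame:
    """Area-weighted regional mean and across-pixel spread per driver.

    Returns a DataFrame with columns (driver, mean_contribution, spread,
    n_pixels).  ``pool_nutrients`` adds a pooled "nutrient" row summing the
    nit and pho shares where both exist.
    """
    names = contributions.attrs.get("drivers", "").split(",")
    rows = []
    share_fields = {k: contributions[f"r_{k}"] for k in names}
    if pool_nutrients and "nit" in share_fields and "pho" in share_fields:
        share_fields["nutrient"] = share_fields["nit"] + share_fields["pho"]
    for name, field in share_fields.items():
        data = field if region_mask is None else field.where(region_mask > 0)
        valid = data.notnull()
        n = int(valid.sum())
        if n == 0:
            raise ValueError("no pixels with defined contributions in region")
        if weighting == "area":
            w = xr.DataArray(
                area_weights(data["lat"].values), dims="lat",
                coords={"lat": data["lat"].values},
            ).broadcast_like(data).where(valid)
        else:
            w = xr.ones_like(data).where(valid)
        mean = float((data * w).sum(skipna=True) / w.sum(skipna=True))
        dev = (data - mean) ** 2
        spread = float(np.sqrt((dev * w).sum(skipna=True) / w.sum(skipna=True)))
        rows.append({"driver": name, "mean_contribution": mean,
                     "spread": spread, "n_pixels": n})
    return pd.DataFrame(rows)
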