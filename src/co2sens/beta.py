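"""Moving-window estimation of GPP sensitivity to CO2 (beta).

Per pixel, annual GPP is regressed on annual CO2, VPD and maximum temperature
(plus an intercept) over sliding 15-year windows:

    GPP = beta * CO2 + a1 * VPD + a2 * Tmax + a3 + eps

The fit is ordinary least squares — the Gaussian maximum-likelihood solution.
The raw CO2 coefficient (GPP units per ppm) is normalized to a relative
sensitivity in % per 100 ppm via the window-mean GPP:

    beta_rel = beta_raw * 100 ppm / mean(GPP) * 100 %

A linear trend fitted through the windowed beta series, labeled by window
center year, summarizes its temporal evolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

#: Condition-number threshold above which a window fit is flagged invalid.
CONDITION_THRESHOLD = 1e8

DEFAULT_WINDOW = 15


@dataclass
class OLSFit:
    """Raw OLS output: coefficients in design-column order, last = intercept."""

    coefs: np.ndarray
    stderr: np.ndarray
    r_squared: float
    p_values: np.ndarray
    condition_number: float
    n: int
    residuals: np.ndarray


@dataclass
class BetaEstimate:
    """Windowed CO2-sensitivity estimate with regression diagnostics."""

    beta_raw: float  # GPP units per ppm
    beta_rel: float  # % per 100 ppm
    a1: float  # VPD coefficient
    a2: float  # Tmax coefficient
    a3: float  # intercept
    r_squared: float
    p_beta: float
    window_center: int
    n_used: int
    condition_number: float
    valid: bool


@dataclass
class TrendResult:
    """OLS slope of a series against time with a two-sided t-test."""

    slope: float
    p_value: float
    significant: bool
    n: int


def ols(X: np.ndarray, y: np.ndarray) -> OLSFit:
    """Least-squares fit of ``y`` on design ``X`` (intercept column included by caller).

    p-values are two-sided t-tests on each coefficient with n - p degrees of
    freedom.  The condition number is the singular-value ratio of ``X``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    coefs, _, rank, sv = np.linalg.lstsq(X, y, rcond=None)
    cond = np.inf if sv[-1] == 0 else float(sv[0] / sv[-1])
    resid = y - X @ coefs
    dof = n - p
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    if rank < p or dof <= 0:
        bad = np.full(p, np.nan)
        return OLSFit(coefs, bad, r2, bad.copy(), cond, n, resid)
    sigma2 = rss / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = coefs / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    return OLSFit(coefs, se, r2, pvals, cond, n, resid)


def fit_window(
    gpp: np.ndarray,
    co2: np.ndarray,
    vpd: np.ndarray,
    tmax: np.ndarray,
    window_center: int | None = None,
    condition_threshold: float = CONDITION_THRESHOLD,
) -> BetaEstimate:
    """Fit the beta regression on one window of aligned annual series.

    A rank-deficient or near-singular design (condition number above
    ``condition_threshold``) yields ``valid=False`` with NaN estimates rather
    than a silently unstable fit.
    """
    gpp, co2, vpd, tmax = (np.asarray(a, dtype=float) for a in (gpp, co2, vpd, tmax))
    n = gpp.size
    if not (co2.size == vpd.size == tmax.size == n):
        raise ValueError("driver series lengths differ within the window")
    center = int(window_center) if window_center is not None else -1
    if np.any(~np.isfinite(np.vstack([gpp, co2, vpd, tmax]))):
        return _invalid_estimate(center, n)
    X = np.column_stack([co2, vpd, tmax, np.ones(n)])
    fit = ols(X, gpp)
    if not np.all(np.isfinite(fit.stderr)) or fit.condition_number > condition_threshold:
        return _invalid_estimate(center, n, fit.condition_number)
    beta_raw = float(fit.coefs[0])
    mean_gpp = float(gpp.mean())
    beta_rel = beta_raw * 100.0 / mean_gpp * 100.0 if mean_gpp != 0 else np.nan
    return BetaEstimate(
        beta_raw=beta_raw,
        beta_rel=beta_rel,
        a1=float(fit.coefs[1]),
        a2=float(fit.coefs[2]),
        a3=float(fit.coefs[3]),
        r_squared=fit.r_squared,
        p_beta=float(fit.p_values[0]),
        window_center=center,
        n_used=n,
        condition_number=fit.condition_number,
        valid=True,
    )


def _invalid_estimate(center: int, n: int, cond: float = np.inf) -> BetaEstimate:
    nan = float("nan")
    return BetaEstimate(nan, nan, nan, nan, nan, nan, nan, center, n, cond, False)


def window_starts(n_years: int, window_len: int, stride: int = 1) -> np.ndarray:
    """Start indices of sliding windows; ``n - window_len + 1`` of them at stride 1."""
    if window_len < 3:
        raise ValueError("window length must be >= 3")
    if n_years < window_len:
        raise ValueError(
            f"series of {n_years} years is shorter than the {window_len}-year window"
        )
    return np.arange(0, n_years - window_len + 1, stride)


def center_year(years: np.ndarray, start: int, window_len: int) -> int:
    """Center label of the window starting at index ``start`` (lower median if even)."""
    return int(years[start + (window_len - 1) // 2])


def moving_beta(
    gpp: np.ndarray,
    co2: np.ndarray,
    vpd: np.ndarray,
    tmax: np.ndarray,
    years: np.ndarray,
    window_len: int = DEFAULT_WINDOW,
    stride: int = 1,
) -> list[BetaEstimate]:
    """Windowed beta estimates for one pixel's aligned annual series.

    Windows containing any non-finite value are skipped (returned invalid).
    """
    years = np.asarray(years, dtype=int)
    _check_year_axis(years, gpp, co2, vpd, tmax)
    estimates = []
    for s in window_starts(years.size, window_len, stride):
        sl = slice(s, s + window_len)
        estimates.append(
            fit_window(
                gpp[sl], co2[sl], vpd[sl], tmax[sl],
                window_center=center_year(years, s, window_len),
            )
        )
    return estimates


def moving_beta_cube(
    gpp: xr.DataArray,
    co2: pd.Series,
    vpd: xr.DataArray,
    tmax: xr.DataArray,
    window_len: int = DEFAULT_WINDOW,
    stride: int = 1,
) -> xr.Dataset:
    """Grid-level moving-window beta: one layer of estimates per window.

    ``co2`` is a scalar annual series indexed by year, shared by all pixels.
    Returns a Dataset with ``beta_rel``, ``beta_raw``, ``a1``, ``a2``, ``a3``,
    ``r_squared``, ``p_beta`` and ``valid`` on dims (window_center, lat, lon).
    """
    years = np.asarray(gpp["year"].values, dtype=int)
    for other in (vpd, tmax):
        if not np.array_equal(np.asarray(other["year"].values, dtype=int), years):
            raise ValueError("GPP, VPD and Tmax cubes must share the year axis")
    co2_vals = co2.reindex(years).to_numpy(dtype=float)
    if np.any(~np.isfinite(co2_vals)):
        missing = [int(y) for y, v in zip(years, co2_vals) if not np.isfinite(v)]
        raise ValueError(f"CO2 series lacks years {missing}")

    starts = window_starts(years.size, window_len, stride)
    centers = np.array([center_year(years, s, window_len) for s in starts])
    nlat, nlon = gpp.sizes["lat"], gpp.sizes["lon"]
    fields = {
        k: np.full((starts.size, nlat, nlon), np.nan)
        for k in ("beta_rel", "beta_raw", "a1", "a2", "a3", "r_squared", "p_beta")
    }
    valid = np.zeros((starts.size, nlat, nlon), dtype=bool)

    gpp_v = gpp.transpose("year", "lat", "lon").values
    vpd_v = vpd.transpose("year", "lat", "lon").values
    tmax_v = tmax.transpose("year", "lat", "lon").values
    for i in range(nlat):
        for j in range(nlon):
            if np.all(~np.isfinite(gpp_v[:, i, j])):
                continue
            for w, s in enumerate(starts):
                sl = slice(s, s + window_len)
                est = fit_window(
                    gpp_v[sl, i, j], co2_vals[sl], vpd_v[sl, i, j],
                    tmax_v[sl, i, j], window_center=centers[w],
                )
                if est.valid:
                    valid[w, i, j] = True
                    for k in fields:
                        fields[k][w, i, j] = getattr(est, k)

    coords = {"window_center": centers, "lat": gpp["lat"].values, "lon": gpp["lon"].values}
    ds = xr.Dataset(
        {k: (("window_center", "lat", "lon"), v) for k, v in fields.items()},
        coords=coords,
    )
    ds["valid"] = (("window_center", "lat", "lon"), valid)
    ds["beta_rel"].attrs["units"] = "% per 100 ppm"
    ds["beta_raw"].attrs["units"] = "GPP units per ppm"
    ds.attrs["window_len"] = window_len
    ds.attrs["stride"] = stride
    return ds


def beta_trend(
    beta_series: np.ndarray,
    centers: np.ndarray,
    alpha: float = 0.05,
) -> TrendResult:
    """Linear trend of a windowed beta series against window-center year.

    Requires at least 3 valid windows; otherwise returns a masked (NaN)
    result.  p-value is the two-sided t-test on the slope (df = n - 2).
    """
    y = np.asarray(beta_series, dtype=float)
    x = np.asarray(centers, dtype=float)
    keep = np.isfinite(y) & np.isfinite(x)
    if keep.sum() < 3:
        return TrendResult(np.nan, np.nan, False, int(keep.sum()))
    res = stats.linregress(x[keep], y[keep])
    pv = float(res.pvalue)
    if np.isnan(pv) and res.stderr == 0:  # exactly collinear input
        pv = 0.0 if res.slope != 0 else 1.0
    return TrendResult(float(res.slope), pv, bool(pv < alpha), int(keep.sum()))


def annualize(
    monthly: xr.DataArray,
    how: str = "mean",
    max_missing: int = 0,
) -> xr.DataArray:
    """Aggregate a monthly cube (datetime ``time`` dim) to calendar years.

    ``how`` is one of ``mean``, ``sum``, ``max``.  Years missing more than
    ``max_missing`` months are masked; otherwise the statistic is computed
    over the available months.
    """
    if how not in ("mean", "sum", "max"):
        raise ValueError(f"unknown aggregation {how!r}")
    grouped = monthly.groupby("time.year")
    agg = getattr(grouped, how)(dim="time", skipna=True)
    present = monthly.notnull().groupby("time.year").sum(dim="time")
    missing = 12 - present  # counts absent and NaN months alike
    agg = agg.where(missing <= max_missing)
    agg.attrs = dict(monthly.attrs)
    agg.attrs["annualized"] = how
    return agg.rename(monthly.name)


def _check_year_axis(years: np.ndarray, *series: np.ndarray) -> None:
    if years.size > 1 and not np.all(np.diff(years) == 1):
        raise ValueError("years must be strictly increasing with step 1")
    for s in series:
        if np.asarray(s).shape[0] != years.size:
            raise ValueError("series length does not match the year axis")
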