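"""Synthetic gridded scenarios with known ground-truth sensitivity.

The generator emulates the statistical structure the analysis assumes: a
near-linear CO2 rise, warming that drives a VPD increase (via a mild negative
RH trend), precipitation rising faster than ET, N deposition that rises then
declines after a break year, slightly rising P deposition, and a GPP field
whose relative sensitivity to CO2 (% per 100 ppm) declines linearly in time.

GPP couples to CO2 through the accumulated relative gain

    gain(t) = integral_0^t beta_rel(s)/100 * dCO2/ds / 100 ds
            = (b0*r*u + b1*r*u^2/2) / 1e4,   u = years since start,

so the instantaneous d(GPP)/d(CO2) equals baseline * beta_rel(t) / 1e4 at
every year.  Over a symmetric window the OLS CO2 coefficient of a quadratic
then equals its central derivative, so the moving-window regression recovers
beta_rel at the window center (exactly, in the absence of GPP noise and
sensitivity trend; to first order otherwise).

All randomness flows from one master seed through per-variable substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from co2sens import vpd as vpd_mod
from co2sens.cubes import make_cube, save_cube, save_dataset

#: Fixed substream order; inserting new variables must append, not reorder.
_STREAMS = ("tas", "tmax", "rh", "precip", "et", "ndep", "pdep", "gpp")

DEFAULT_DRIVER_NOISE = {
    "tas": 0.3,    # degC interannual variability
    "tmax": 0.6,   # degC
    "rh": 2.5,     # %
    "precip": 2.0, # mm/month
    "et": 1.0,     # mm/month
    "ndep": 20.0,  # mg m-2 yr-1
    "pdep": 1.0,   # mg m-2 yr-1
}


@dataclass
class ScenarioConfig:
    """Knobs of the synthetic scenario; defaults echo observed magnitudes
    (VPD trend of order 0.013 hPa/yr, precipitation trend 0.044 mm/month/yr,
    N deposition declining after 1990)."""

    n_lat: int = 10
    n_lon: int = 10
    lat_range: tuple[float, float] = (30.0, 80.0)
    lon_range: tuple[float, float] = (-180.0, 180.0)
    year_start: int = 1982
    year_end: int = 2015
    co2_start: float = 341.0
    co2_rate: float = 1.8          # ppm/yr
    beta_rel_start: float = 5.0    # % per 100 ppm
    beta_rel_trend: float = -0.05  # % per 100 ppm per yr
    tas_trend: float = 0.03        # degC/yr
    rh_trend: float = -0.05        # %/yr
    precip_trend: float = 0.044    # mm/month/yr
    et_trend: float = 0.02         # mm/month/yr
    ndep_breakyear: int = 1990
    noise_sd_gpp: float = 0.01     # fraction of baseline GPP
    noise_sd_drivers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DRIVER_NOISE)
    )
    seed: int = 0
    # baselines and couplings
    gpp_baseline: float = 1000.0   # flux units
    gpp_lat_gradient: float = -3.0 # flux units per degree latitude
    gpp_vpd_coef: float = -5.0     # flux units per hPa
    gpp_tmax_coef: float = 2.0     # flux units per degC
    tas_base: float = 12.0         # degC at the southern edge
    tas_lat_gradient: float = -0.15
    tmax_offset: float = 8.0
    rh_base: float = 70.0
    precip_base: float = 60.0
    et_base: float = 40.0
    ndep_base: float = 600.0
    ndep_rise: float = 10.0        # mg m-2 yr-1 per yr before the break
    ndep_decline: float = 8.0      # mg m-2 yr-1 per yr after the break
    pdep_base: float = 30.0
    pdep_trend: float = 0.3
    window_len: int = 15

    def validate(self) -> None:
        n_years = self.year_end - self.year_start + 1
        if n_years < self.window_len:
            raise ValueError(
                f"{n_years} simulated years is fewer than the "
                f"{self.window_len}-year window"
            )
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.noise_sd_gpp < 0 or any(v < 0 for v in self.noise_sd_drivers.values()):
            raise ValueError("noise scales must be >= 0")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def lats(self) -> np.ndarray:
        lo, hi = self.lat_range
        return np.linspace(lo, hi, self.n_lat)

    @property
    def lons(self) -> np.ndarray:
        lo, hi = self.lon_range
        # cell centers, avoiding a duplicate at the wrap-around
        return lo + (np.arange(self.n_lon) + 0.5) * (hi - lo) / self.n_lon


@dataclass
class SyntheticTruth:
    """Generating quantities for parameter-recovery tests."""

    beta_rel_true: xr.DataArray       # (year, lat, lon), % per 100 ppm
    beta_raw_true: xr.DataArray       # (year, lat, lon), flux units per ppm
    coefficients_true: dict[str, xr.DataArray]  # per-pixel vpd/tmax coefs, baseline

    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset(
            {"beta_rel_true": self.beta_rel_true, "beta_raw_true": self.beta_raw_true}
        )
        for name, da in self.coefficients_true.items():
            ds[f"coef_{name}_true"] = da
        return ds


@dataclass
class Scenario:
    cubes: dict[str, xr.DataArray]
    co2: pd.Series
    truth: SyntheticTruth
    config: ScenarioConfig


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def co2_series(config: ScenarioConfig) -> pd.Series:
    """Deterministic near-linear annual CO2 record (ppm)."""
    u = config.years - config.year_start
    s = pd.Series(config.co2_start + config.co2_rate * u, index=config.years, name="co2")
    s.index.name = "year"
    return s


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate driver cubes, a CO2 series and the ground truth.

    Identical config and seed give bit-identical output.
    """
    config.validate()
    rngs = _rngs(config.seed)
    years, lats, lons = config.years, config.lats, config.lons
    ny, nlat, nlon = years.size, lats.size, lons.size
    u = (years - config.year_start)[:, None, None].astype(float)
    noise = config.noise_sd_drivers

    def draw(name: str) -> np.ndarray:
        sd = noise.get(name, 0.0)
        return rngs[name].normal(0.0, sd, size=(ny, nlat, nlon)) if sd > 0 else 0.0

    tas0 = config.tas_base + config.tas_lat_gradient * (lats - lats[0])
    tas = tas0[None, :, None] + config.tas_trend * u + draw("tas")
    tmax = tas + config.tmax_offset + draw("tmax")
    rh = np.clip(config.rh_base + config.rh_trend * u + draw("rh"), 1.0, 100.0)
    precip = np.clip(config.precip_base + config.precip_trend * u + draw("precip"), 0.0, None)
    et = np.clip(config.et_base + config.et_trend * u + draw("et"), 0.0, None)

    ub = float(config.ndep_breakyear - config.year_start)
    hinge = np.where(u <= ub, config.ndep_rise * u,
                     config.ndep_rise * ub - config.ndep_decline * (u - ub))
    ndep = np.clip(config.ndep_base + hinge + draw("ndep"), 0.0, None)
    pdep = np.clip(config.pdep_base + config.pdep_trend * u + draw("pdep"), 0.0, None)

    vpd_field = vpd_mod.vpd(tas, rh)

    baseline = config.gpp_baseline + config.gpp_lat_gradient * (lats - lats[0])
    baseline = np.broadcast_to(baseline[None, :, None], (ny, nlat, nlon))
    b0, b1, r = config.beta_rel_start, config.beta_rel_trend, config.co2_rate
    beta_rel_t = b0 + b1 * u  # (ny, 1, 1)
    gain = (b0 * r * u + 0.5 * b1 * r * u**2) / 1e4
    gpp = (
        baseline * (1.0 + gain)
        + config.gpp_vpd_coef * vpd_field
        + config.gpp_tmax_coef * tmax
    )
    if config.noise_sd_gpp > 0:
        gpp = gpp + rngs["gpp"].normal(
            0.0, config.noise_sd_gpp * config.gpp_baseline, size=(ny, nlat, nlon)
        )

    cube = lambda v, name, units: make_cube(
        np.broadcast_to(v, (ny, nlat, nlon)).copy(), years, lats, lons, name, units
    )
    cubes = {
        "gpp": cube(gpp, "gpp", "gC m-2 yr-1"),
        "tas": cube(tas, "tas", "degC"),
        "tmax": cube(tmax, "tmax", "degC"),
        "rh": cube(rh, "rh", "%"),
        "precip": cube(precip, "precip", "mm month-1"),
        "et": cube(et, "et", "mm month-1"),
        "ndep": cube(ndep, "ndep", "mg m-2 yr-1"),
        "pdep": cube(pdep, "pdep", "mg m-2 yr-1"),
    }

    beta_rel_true = cube(
        np.broadcast_to(beta_rel_t, (ny, nlat, nlon)), "beta_rel_true", "% per 100 ppm"
    )
    beta_raw_true = cube(
        baseline * beta_rel_t / 1e4, "beta_raw_true", "flux units per ppm"
    )
    pixel = lambda v, name, units: xr.DataArray(
        np.broadcast_to(np.asarray(v, dtype=float), (nlat, nlon)).copy(),
        dims=("lat", "lon"), coords={"lat": lats, "lon": lons},
        name=name, attrs={"units": units},
    )
    truth = SyntheticTruth(
        beta_rel_true=beta_rel_true,
        beta_raw_true=beta_raw_true,
        coefficients_true={
            "vpd": pixel(config.gpp_vpd_coef, "coef_vpd_true", "flux units per hPa"),
            "tmax": pixel(config.gpp_tmax_coef, "coef_tmax_true", "flux units per degC"),
            "baseline": pixel(baseline[0], "baseline_gpp", "gC m-2 yr-1"),
        },
    )
    return Scenario(cubes=cubes, co2=co2_series(config), truth=truth, config=config)


def implied_vpd_trend(config: ScenarioConfig) -> xr.DataArray:
    """Noise-free per-pixel OLS slope of the generated VPD series (hPa/yr).

    Serves as the deterministic reference the noisy-ensemble VPD trends
    should scatter around.
    """
    from dataclasses import replace

    quiet = replace(
        config,
        noise_sd_gpp=0.0,
        noise_sd_drivers={k: 0.0 for k in config.noise_sd_drivers},
    )
    scen = generate_scenario(quiet)
    tas = scen.cubes["tas"]
    rh = scen.cubes["rh"]
    v = vpd_mod.vpd(tas, rh)
    years = v["year"].values.astype(float)
    x = years - years.mean()
    slope = (v * xr.DataArray(x, dims="year")).sum("year") / float((x**2).sum())
    slope.attrs["units"] = "hPa per year"
    return slope


def disaggregate_monthly(annual: xr.DataArray) -> xr.DataArray:
    """Trivial monthly disaggregation: repeat each annual value 12 times."""
    years = annual["year"].values
    time = pd.to_datetime(
        [f"{int(y)}-{m:02d}-15" for y in years for m in range(1, 13)]
    )
    data = np.repeat(annual.transpose("year", "lat", "lon").values, 12, axis=0)
    out = xr.DataArray(
        data, dims=("time", "lat", "lon"),
        coords={"time": time, "lat": annual["lat"].values, "lon": annual["lon"].values},
        name=annual.name, attrs=dict(annual.attrs),
    )
    return out


def write_scenario(scenario: Scenario, outdir: str | Path) -> dict[str, Path]:
    """Write one NetCDF per driver variable, co2.csv, and a separate truth file.

    The truth file is kept out of the returned driver-file mapping (under the
    ``"__truth__"`` key) so pipelines cannot accidentally consume it.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, cube in scenario.cubes.items():
        p = outdir / f"{name}.nc"
        save_cube(cube, p)
        paths[name] = p
    co2_path = outdir / "co2.csv"
    scenario.co2.rename("ppm").to_csv(co2_path)
    paths["co2"] = co2_path
    truth_path = outdir / "ground_truth.nc"
    save_dataset(scenario.truth.to_dataset(), truth_path)
    paths["__truth__"] = truth_path
    cfg_path = outdir / "scenario_config.yaml"
    _write_config(scenario.config, cfg_path)
    paths["__config__"] = cfg_path
    return paths


def _write_config(config: ScenarioConfig, path: Path) -> None:
    import yaml

    d = asdict(config)
    d["lat_range"] = list(d["lat_range"])
    d["lon_range"] = list(d["lon_range"])
    path.write_text(yaml.safe_dump(d, sort_keys=True))


def config_from_file(path: str | Path) -> ScenarioConfig:
    import yaml

    d = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("lat_range", "lon_range"):
        if key in d:
            d[key] = tuple(d[key])
    return ScenarioConfig(**d)


def generate_attribution_windows(
    n_windows: int = 20,
    n_lat: int = 10,
    n_lon: int = 10,
    shares: dict[str, float] | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, dict[str, np.ndarray], dict[str, float]]:
    """Windowed beta/driver arrays with a prescribed driver variance share.

    Each driver is an independent Gaussian series per pixel; coefficients are
    chosen so the generating standardized-coefficient share of driver X
    equals ``shares[X]`` exactly (|c_X| * sd_X normalized).  ``noise_sd`` is
    the residual sd as a fraction of the generated beta sd.  Returns
    ``(beta, drivers, true_shares)`` with beta of shape
    (n_windows, n_lat, n_lon).
    """
    if shares is None:
        shares = {"vpd": 0.7, "wa": 0.15, "nit": 0.1, "pho": 0.05}
    total = sum(shares.values())
    true_shares = {k: v / total for k, v in shares.items()}
    rng = np.random.default_rng(seed)
    drivers: dict[str, np.ndarray] = {}
    beta = np.zeros((n_windows, n_lat, n_lon))
    for name, share in true_shares.items():
        x = rng.normal(size=(n_windows, n_lat, n_lon))
        x = (x - x.mean(axis=0)) / x.std(axis=0)  # unit sample sd per pixel
        drivers[name] = x
        beta = beta + share * x  # coefficient = share, sd = 1 by construction
    if noise_sd > 0:
        beta = beta + rng.normal(
            0.0, noise_sd * beta.std(), size=beta.shape
        )
    return beta, drivers, true_shares
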