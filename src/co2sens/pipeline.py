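"""End-to-end pipeline driver.

Sequences the stages annualize (if monthly input) -> VPD -> moving-window
beta -> beta trend -> driver attribution -> regional summaries, writing every
gridded product as NetCDF and scalar summaries as CSV.  Each output embeds
the configuration hash; identical config + seed reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

import co2sens
from co2sens import attribution, beta as beta_mod, spatial, vpd as vpd_mod
from co2sens.config import PipelineConfig
from co2sens.cubes import load_co2_series, load_cube, save_dataset
from co2sens.synthetic import generate_scenario, write_scenario

logger = logging.getLogger(__name__)

CSV_FLOAT_FORMAT = "%.10g"


class StageError(RuntimeError):
    """Failure inside a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the full analysis; returns a mapping of artifact names to paths."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    artifacts: dict[str, Path] = {}

    cubes, co2 = _stage_load(config, outdir, artifacts)

    logger.info("stage vpd: start")
    try:
        if "vpd" in cubes:
            vpd_cube = cubes["vpd"]
        elif config.humidity_kind == "avp":
            vpd_cube = vpd_mod.vpd_cube(cubes["tas"], cubes["avp"], humidity_kind="avp")
        else:
            vpd_cube = vpd_mod.vpd_cube(cubes["tas"], cubes["rh"], humidity_kind="rh")
    except KeyError as exc:
        raise StageError("vpd", f"missing input cube {exc}") from exc
    _write(vpd_cube.to_dataset(name="vpd"), outdir / "vpd.nc", cfg_hash, artifacts, "vpd")
    logger.info("stage vpd: done")

    logger.info("stage beta: start")
    try:
        beta_ds = beta_mod.moving_beta_cube(
            cubes["gpp"], co2, vpd_cube, cubes["tmax"],
            window_len=config.window_len, stride=config.stride,
        )
    except KeyError as exc:
        raise StageError("beta", f"missing input cube {exc}") from exc
    n_invalid = int((~beta_ds["valid"]).sum())
    logger.info("stage beta: done (%d invalid window fits)", n_invalid)
    _write(beta_ds, outdir / "beta.nc", cfg_hash, artifacts, "beta")

    logger.info("stage trend: start")
    beta_trend = spatial.pixel_trend_map(
        beta_ds["beta_rel"], dim="window_center", alpha=config.alpha
    )
    _write(beta_trend, outdir / "beta_trend.nc", cfg_hash, artifacts, "beta_trend")
    vpd_trend = spatial.pixel_trend_map(vpd_cube, dim="year", alpha=config.alpha)
    _write(vpd_trend, outdir / "vpd_trend.nc", cfg_hash, artifacts, "vpd_trend")
    logger.info("stage trend: done (%d masked pixels)",
                int(beta_trend["slope"].isnull().sum()))

    logger.info("stage attribute: start")
    drivers = _driver_cubes(config, cubes, vpd_cube)
    contrib = attribution.attribute_cube(
        beta_ds["beta_rel"], drivers,
        window_len=config.window_len, stride=config.stride,
    )
    _write(contrib, outdir / "attribution.nc", cfg_hash, artifacts, "attribution")
    logger.info("stage attribute: done (%d masked pixels)",
                int(contrib[f"r_{list(drivers)[0]}"].isnull().sum()))

    logger.info("stage report: start")
    _stage_report(config, beta_ds, beta_trend, vpd_trend, contrib,
                  cfg_hash, outdir, artifacts)
    logger.info("stage report: done")

    provenance = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "package_version": co2sens.__version__,
        "config": config.to_dict(),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    prov_path = outdir / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=2, sort_keys=True, default=str))
    artifacts["provenance"] = prov_path
    return artifacts


def _stage_load(config, outdir, artifacts):
    logger.info("stage load: start")
    if config.simulate is not None:
        scen_cfg = config.simulate
        scenario = generate_scenario(scen_cfg)
        paths = write_scenario(scenario, outdir / "scenario")
        for k, p in paths.items():
            artifacts[f"scenario_{k.strip('_')}"] = p
        cubes = dict(scenario.cubes)
        co2 = scenario.co2
    else:
        cubes = {}
        co2 = None
        for logical, path in config.inputs.items():
            if not Path(path).exists():
                raise StageError("load", f"input file for {logical!r} not found: {path}")
            if logical == "co2":
                co2 = load_co2_series(path)
            else:
                cubes[logical] = load_cube(path, config.var_map.get(logical))
        if co2 is None:
            raise StageError("load", "no CO2 series among the inputs")
    logger.info("stage load: done (%d cubes)", len(cubes))
    return cubes, co2


def _driver_cubes(config, cubes, vpd_cube) -> dict[str, xr.DataArray]:
    try:
        wa = cubes["precip"] - cubes["et"]
    except KeyError as exc:
        raise StageError("attribute", f"missing input cube {exc}") from exc
    wa.attrs["units"] = cubes["precip"].attrs.get("units", "mm")
    drivers = {"vpd": vpd_cube, "wa": wa}
    if config.mode == "historical":
        try:
            drivers["nit"] = cubes["ndep"]
            drivers["pho"] = cubes["pdep"]
        except KeyError as exc:
            raise StageError("attribute", f"missing input cube {exc}") from exc
    else:  # future mode: soil N replaces the deposition pair
        try:
            drivers["soil_n"] = cubes["soil_n"]
        except KeyError as exc:
            raise StageError("attribute", f"missing input cube {exc}") from exc
    return drivers


def _stage_report(config, beta_ds, beta_trend, vpd_trend, contrib,
                  cfg_hash, outdir, artifacts):
    rows = []
    region = None
    for name, trend in (("beta_rel", beta_trend), ("vpd", vpd_trend)):
        for sign in ("negative", "positive"):
            for sig_only in (False, True):
                frac = spatial.fraction_with_trend(
                    trend, sign=sign, significant_only=sig_only
                )
                rows.append({
                    "variable": name, "sign": sign,
                    "significant_only": sig_only, "area_fraction": frac,
                })
    fractions = pd.DataFrame(rows)
    _write_csv(fractions, outdir / "trend_fractions.csv", cfg_hash)
    artifacts["trend_fractions"] = outdir / "trend_fractions.csv"

    mean_beta = spatial.area_weighted_mean(beta_ds["beta_rel"], region)
    series = pd.DataFrame({
        "window_center": beta_ds["window_center"].values,
        "mean_beta_rel": np.asarray(mean_beta),
    })
    _write_csv(series, outdir / "regional_beta_series.csv", cfg_hash)
    artifacts["regional_beta_series"] = outdir / "regional_beta_series.csv"

    summary = attribution.regional_contribution_summary(
        contrib, pool_nutrients=(config.mode == "historical")
    )
    _write_csv(summary, outdir / "contribution_summary.csv", cfg_hash)
    artifacts["contribution_summary"] = outdir / "contribution_summary.csv"


def _write(ds: xr.Dataset, path: Path, cfg_hash: str, artifacts: dict, name: str):
    ds = ds.copy()
    ds.attrs["config_hash"] = cfg_hash
    # bool variables are not representable in NetCDF3
    for var in ds.data_vars:
        if ds[var].dtype == bool:
            ds[var] = ds[var].astype("int8")
    save_dataset(ds, path)
    artifacts[name] = path


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, index=False, float_format=CSV_FLOAT_FORMAT, lineterminator="\n")
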