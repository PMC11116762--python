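"""Vapor-pressure and assimilation physics.

Saturated vapor pressure uses the 6.112 hPa Magnus-type expression with a
pressure-dependent enhancement factor; air pressure follows a barometric
altitude correction anchored at 1013.25 hPa sea-level pressure.  VPD is the
difference between saturated and actual vapor pressure; both a relative-
humidity path and a direct actual-vapor-pressure path are provided and agree
on consistent inputs.

All temperature arguments are in degrees Celsius; inputs in Kelvin must be
converted at ingestion (subtract 273.15).  Functions operate elementwise on
scalars, NumPy arrays, and xarray objects.
"""

from __future__ import annotations

import logging

import numpy as np
import xarray as xr

logger = logging.getLogger(__name__)

#: Air pressure at mean sea level, hPa.
SEA_LEVEL_PRESSURE = 1013.25

#: Lapse-rate constant (K per m) in the barometric altitude correction.
_LAPSE = 0.0065

# The barometric formula is anchored at 273.16 K (as published for this
# pipeline) while Celsius/Kelvin conversion elsewhere uses 273.15.
_T_ANCHOR = 273.16


def air_pressure(tas, elevation=0.0):
    """Air pressure (hPa) at altitude ``elevation`` (m) and temperature ``tas`` (degC).

    ``Pa = Pasl * ((Tas + 273.16) / (Tas + 273.16 + 0.0065 * H)) ** 5.625``.
    Decreases monotonically with altitude; equals 1013.25 hPa at H = 0.
    """
    tas = _check_temperature(tas, limit=-273.15)
    elevation = np.asarray(elevation) if not isinstance(elevation, xr.DataArray) else elevation
    if np.any(np.asarray(elevation) < 0):
        raise ValueError("elevation must be >= 0 m")
    tk = tas + _T_ANCHOR
    return SEA_LEVEL_PRESSURE * (tk / (tk + _LAPSE * elevation)) ** 5.625


def enhancement_factor(pa):
    """Dimensionless moist-air enhancement factor ``f = 1 + 7e-4 + 3.46e-6 * Pa``."""
    return 1.0 + 7e-4 + 3.46e-6 * pa


def saturated_vapor_pressure(tas, pa=SEA_LEVEL_PRESSURE):
    """Saturated vapor pressure (hPa) at temperature ``tas`` (degC), pressure ``pa`` (hPa).

    ``SVP = 6.112 * f(Pa) * exp(17.67 * Tas / (Tas + 243.5))``.
    """
    tas = _check_temperature(tas, limit=-243.5)
    return 6.112 * enhancement_factor(pa) * np.exp(17.67 * tas / (tas + 243.5))


def actual_vapor_pressure(rh, svp, clip_supersaturation=True):
    """Actual vapor pressure (hPa): ``AVP = RH/100 * SVP``.

    ``rh`` is relative humidity in percent.  Values slightly above 100
    (reanalysis supersaturation artifacts) are clipped to 100 with a logged
    warning when ``clip_supersaturation`` is true; out-of-range values raise
    otherwise.  Negative RH always raises.
    """
    rh = _check_rh(rh, clip_supersaturation)
    return rh / 100.0 * svp


def vpd(tas, rh, elevation=0.0, clip_supersaturation=True):
    """Vapor pressure deficit (hPa) from temperature (degC), RH (%), altitude (m).

    VPD = SVP - AVP; zero at RH = 100 and non-negative for RH <= 100.
    """
    pa = air_pressure(tas, elevation)
    svp = saturated_vapor_pressure(tas, pa)
    avp = actual_vapor_pressure(rh, svp, clip_supersaturation)
    return svp - avp


def vpd_from_avp(tas, avp, elevation=0.0):
    """Vapor pressure deficit (hPa) when actual vapor pressure is observed directly."""
    if np.any(np.asarray(avp) < 0):
        raise ValueError("actual vapor pressure must be >= 0 hPa")
    pa = air_pressure(tas, elevation)
    svp = saturated_vapor_pressure(tas, pa)
    return svp - avp


def assimilation_rate(transpiration, ca, ci, vpd_value):
    """CO2 assimilation rate ``A = T * Ca / (1.6 * VPD) * (1 - Ci/Ca)``.

    ``ca``/``ci`` are ambient / inner-leaf CO2 partial pressures.  A is
    inversely proportional to VPD at fixed transpiration and partial
    pressures, vanishing when Ci = Ca.
    """
    if np.any(np.asarray(vpd_value) <= 0):
        raise ValueError("assimilation rate requires VPD > 0")
    if np.any(np.asarray(ca) <= 0):
        raise ValueError("ambient CO2 partial pressure must be > 0")
    return transpiration * ca / (1.6 * vpd_value) * (1.0 - ci / ca)


def vpd_cube(tas_cube, humidity_cube, elevation=None, humidity_kind="rh"):
    """Compute a VPD cube from co-registered temperature and humidity cubes.

    ``humidity_kind`` selects the input dialect: ``"rh"`` for relative
    humidity in percent, ``"avp"`` for actual vapor pressure in hPa.
    ``elevation`` may be None (sea level), a scalar, or a (lat, lon) grid.
    """
    if humidity_kind not in ("rh", "avp"):
        raise ValueError(f"unknown humidity kind {humidity_kind!r}")
    h = 0.0 if elevation is None else elevation
    if humidity_kind == "rh":
        out = vpd(tas_cube, humidity_cube, elevation=h)
    else:
        out = vpd_from_avp(tas_cube, humidity_cube, elevation=h)
    out = out.rename("vpd")
    out.attrs["units"] = "hPa"
    return out


def _check_temperature(tas, limit):
    arr = np.asarray(tas if not isinstance(tas, xr.DataArray) else tas.values)
    if np.any(arr[np.isfinite(arr)] <= limit):
        raise ValueError(f"temperature must exceed {limit} degC")
    return tas


def _check_rh(rh, clip_supersaturation):
    arr = np.asarray(rh if not isinstance(rh, xr.DataArray) else rh.values)
    finite = arr[np.isfinite(arr)]
    if np.any(finite < 0):
        raise ValueError("relative humidity must be >= 0 %")
    if np.any(finite > 100):
        if not clip_supersaturation:
            raise ValueError("relative humidity above 100 % (clipping disabled)")
        n = int(np.sum(finite > 100))
        logger.warning("clipping %d supersaturated RH values to 100 %%", n)
        rh = rh.clip(max=100) if isinstance(rh, xr.DataArray) else np.minimum(rh, 100)
    return rh
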