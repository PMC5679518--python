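"""Explanatory variables of the surrogate: seasonal air temperatures,
FAO-56 reference evapotranspiration, water clarity and lake geometry.

The surrogate regresses MWAT above the thermocline on a small set of
predictors available for any surveyed lake: mean July-August air
temperature (summer heat input), mean January air temperature (a proxy for
the ice regime), annual reference evapotranspiration (integrating radiation,
humidity and wind), the light extinction coefficient, and lake geometry --
either the geometry ratio Area^0.25 / H_max (area in m^2, units m^-0.5;
values below ~10 mark small, deep, strongly stratifying lakes) or raw depth
and area.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic_lake import (
    DAYS_PER_YEAR,
    ClimateSeries,
    LakeConfig,
    saturation_vapor_pressure,
    surface_pressure,
    vapor_pressure_from_specific_humidity,
)

#: July-August window on the 365-day calendar (1-based day-of-year, inclusive)
JULY_AUG_DOY = (182, 243)
JAN_DOY = (1, 31)

#: default predictor set fed to the Gaussian Process
FEATURES_DEFAULT = ("t_july_aug", "t_jan", "pet", "extinction",
                    "geometry_ratio", "max_depth")
#: alternative set carrying raw depth and area instead of the geometry ratio
FEATURES_DEPTH_AREA = ("t_july_aug", "t_jan", "pet", "extinction",
                       "max_depth", "surface_area")


@dataclass(frozen=True)
class FeatureVector:
    """Predictors of one (lake x climate) combination."""

    t_july_aug: float       # degC
    t_jan: float            # degC
    pet: float              # mm yr-1, mean annual reference ET
    extinction: float       # m-1
    geometry_ratio: float   # m^-0.5
    max_depth: float        # m
    surface_area: float     # m^2

    def __post_init__(self):
        vals = (self.t_july_aug, self.t_jan, self.pet, self.extinction,
                self.geometry_ratio, self.max_depth, self.surface_area)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("non-finite feature values")
        if self.geometry_ratio <= 0:
            raise ValueError("geometry ratio must be positive")

    def to_array(self, feature_names=FEATURES_DEFAULT) -> np.ndarray:
        return np.array([getattr(self, name) for name in feature_names])


def geometry_ratio(surface_area: float, max_depth: float) -> float:
    """Geometry ratio Area^0.25 / H_max (area in m^2, depth in m)."""
    if surface_area <= 0 or max_depth <= 0:
        raise ValueError("surface_area and max_depth must be positive")
    return surface_area ** 0.25 / max_depth


def seasonal_air_means(climate: ClimateSeries):
    """Multi-year mean daily air temperature over July-August and January."""
    doy = climate.doy
    ja = (doy >= JULY_AUG_DOY[0]) & (doy <= JULY_AUG_DOY[1])
    jan = (doy >= JAN_DOY[0]) & (doy <= JAN_DOY[1])
    return float(climate.tmean[ja].mean()), float(climate.tmean[jan].mean())


# ---------------------------------------------------------------------------
# FAO-56 Penman-Monteith reference evapotranspiration
# ---------------------------------------------------------------------------

_SOLAR_CONSTANT = 0.0820       # MJ m-2 min-1
_STEFAN_BOLTZMANN = 4.903e-9   # MJ K-4 m-2 d-1
_ALBEDO = 0.23


def extraterrestrial_radiation(latitude_deg, doy):
    """Daily extraterrestrial radiation Ra (MJ m-2 d-1)."""
    lat = math.radians(latitude_deg)
    doy = np.asarray(doy, dtype=float)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    decl = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    x = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    ws = np.arccos(x)
    return (24.0 * 60.0 / np.pi) * _SOLAR_CONSTANT * dr * (
        ws * math.sin(lat) * np.sin(decl)
        + math.cos(lat) * np.cos(decl) * np.sin(ws))


def pet_fao56_daily(tmax, tmin, specific_humidity, shortwave, wind_2m,
                    elevation: float, latitude: float, doy) -> np.ndarray:
    """Daily FAO-56 Penman-Monteith reference-crop evapotranspiration (mm/d).

    Implements the standard daily ET0 equation

        ET0 = [0.408 D (Rn - G) + g * 900/(T+273) * u2 * (es - ea)]
              / [D + g (1 + 0.34 u2)]

    with the slope of the vapour-pressure curve D at mean temperature,
    psychrometric constant g from barometric pressure at ``elevation``,
    es as the mean of saturation pressures at tmax and tmin, ea from
    specific humidity, net radiation from measured shortwave with the
    FAO-56 net-longwave formula (clear-sky radiation from extraterrestrial
    radiation Ra at ``latitude``), soil heat flux G = 0 at the daily step,
    and the result floored at zero. Supersaturated inputs (ea > es) are
    clipped to saturation with a warning.
    """
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    shortwave = np.asarray(shortwave, dtype=float)
    wind_2m = np.asarray(wind_2m, dtype=float)
    if np.any(tmin > tmax):
        raise ValueError("tmin must not exceed tmax")

    tmean = (tmax + tmin) / 2.0
    delta = (4098.0 * saturation_vapor_pressure(tmean)
             / (tmean + 237.3) ** 2)
    pressure = surface_pressure(elevation)
    gamma = 0.000665 * pressure

    es = (saturation_vapor_pressure(tmax) + saturation_vapor_pressure(tmin)) / 2.0
    ea = vapor_pressure_from_specific_humidity(specific_humidity, pressure)
    if np.any(ea > es):
        warnings.warn("supersaturated humidity input; actual vapour pressure "
                      "clipped to saturation", stacklevel=2)
        ea = np.minimum(ea, es)

    ra = extraterrestrial_radiation(latitude, doy)
    rso = (0.75 + 2e-5 * elevation) * ra
    # relative shortwave bounded to [0.3, 1] as in the reference standard
    rel = np.clip(np.where(rso > 0, shortwave / np.where(rso > 0, rso, 1.0), 0.3),
                  0.3, 1.0)
    rns = (1.0 - _ALBEDO) * shortwave
    rnl = (_STEFAN_BOLTZMANN
           * ((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4) / 2.0
           * (0.34 - 0.14 * np.sqrt(ea))
           * (1.35 * rel - 0.35))
    rn = rns - rnl

    num = 0.408 * delta * rn + gamma * (900.0 / (tmean + 273.0)) * wind_2m * (es - ea)
    den = delta + gamma * (1.0 + 0.34 * wind_2m)
    return np.maximum(num / den, 0.0)


def annual_pet(climate: ClimateSeries, elevation: float | None = None,
               latitude: float | None = None) -> float:
    """Mean annual total reference evapotranspiration (mm/yr) of a series."""
    elevation = climate.elevation if elevation is None else elevation
    latitude = climate.latitude if latitude is None else latitude
    et0 = pet_fao56_daily(climate.tmax, climate.tmin, climate.specific_humidity,
                          climate.shortwave, climate.wind, elevation, latitude,
                          climate.doy)
    return float(et0.sum() / climate.n_years)


def assemble_features(lake: LakeConfig, climate: ClimateSeries) -> FeatureVector:
    """Build the full predictor vector for one lake under one climate.

    PET uses the climate location's elevation and latitude (the forcing is
    defined there); geometry and clarity come from the lake.
    """
    t_ja, t_jan = seasonal_air_means(climate)
    pet = annual_pet(climate)
    return FeatureVector(
        t_july_aug=t_ja, t_jan=t_jan, pet=pet,
        extinction=lake.extinction,
        geometry_ratio=geometry_ratio(lake.surface_area, lake.max_depth),
        max_depth=lake.max_depth, surface_area=lake.surface_area,
    )
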