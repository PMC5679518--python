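"""Synthetic climate forcing and a two-layer daily lake thermal simulator.

This module is the "teacher" of the surrogate pipeline: it generates daily
meteorological series with seasonal cycles, AR(1) weather noise and additive
monthly warming deltas, and integrates a deliberately simple two-layer
(epilimnion / hypolimnion) energy balance that reproduces the qualitative
behaviour the surrogate must learn:

* epilimnion temperature relaxes toward an equilibrium set by air
  temperature, absorbed shortwave radiation and evaporative cooling;
* mixed-layer depth deepens with fetch, shoals with water clarity and with
  the strength of stratification;
* strongly stratified, clear lakes develop a cool layer just above the
  thermocline (a "secondary thermocline" shading effect), which is where the
  habitat-relevant daily maximum is evaluated;
* ice is represented as a 0 degC floor with attenuated surface exchange.

The simulator is *not* a hydrodynamic model: it is a smooth, physically
plausible stand-in whose coefficients are frozen constants (``SimulatorParams``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365
#: cumulative days at the start of each month on the 365-day calendar
_MONTH_STARTS = np.array([0, 31, 59, 90, 120, 151, 181, 212, 243, 273, 304, 334, 365])
_MONTH_OF_DOY = np.searchsorted(_MONTH_STARTS[1:], np.arange(DAYS_PER_YEAR), side="right")

# training envelope of the lake design space
DEPTH_RANGE = (2.0, 30.0)            # m
AREA_RANGE = (1e5, 1e8)              # m^2 (0.1 - 100 km^2)
EXTINCTION_RANGE = (0.2, 4.0)        # m^-1, clear to turbid


def saturation_vapor_pressure(temp_c):
    """Tetens saturation vapour pressure (kPa) at air/water temperature in degC."""
    temp_c = np.asarray(temp_c, dtype=float)
    return 0.6108 * np.exp(17.27 * temp_c / (temp_c + 237.3))


def surface_pressure(elevation_m: float) -> float:
    """Barometric pressure (kPa) at elevation, standard-atmosphere profile."""
    return 101.3 * ((293.0 - 0.0065 * elevation_m) / 293.0) ** 5.26


def vapor_pressure_from_specific_humidity(q, pressure_kpa):
    """Actual vapour pressure (kPa) from specific humidity (kg/kg)."""
    q = np.asarray(q, dtype=float)
    return q * pressure_kpa / (0.622 + 0.378 * q)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LakeConfig:
    """Morphometry and clarity of one lake: the 3-D design space of the study."""

    lake_id: str
    max_depth: float          # m
    surface_area: float       # m^2
    extinction: float         # m^-1
    elevation: float = 0.0    # m
    latitude: float = 40.0    # deg N

    def __post_init__(self):
        if not (self.max_depth > 0 and self.surface_area > 0 and self.extinction > 0):
            raise ValueError("max_depth, surface_area and extinction must be positive")
        if not all(math.isfinite(v) for v in
                   (self.max_depth, self.surface_area, self.extinction)):
            raise ValueError("non-finite lake parameters")

    @property
    def fetch(self) -> float:
        """Characteristic fetch (m), the square root of surface area."""
        return math.sqrt(self.surface_area)

    def in_training_envelope(self) -> bool:
        return (DEPTH_RANGE[0] <= self.max_depth <= DEPTH_RANGE[1]
                and AREA_RANGE[0] <= self.surface_area <= AREA_RANGE[1])


@dataclass(frozen=True)
class ScenarioDelta:
    """Monthly change signal of one climate scenario.

    ``monthly_dt`` is added to daily air temperature; ``monthly_sw_factor``
    multiplies daily shortwave radiation. The identity scenario (all zeros,
    all ones) is the historical baseline.
    """

    scenario_id: str
    monthly_dt: tuple = (0.0,) * 12
    monthly_sw_factor: tuple = (1.0,) * 12

    def __post_init__(self):
        if len(self.monthly_dt) != 12 or len(self.monthly_sw_factor) != 12:
            raise ValueError("monthly_dt and monthly_sw_factor need 12 entries")
        if not all(math.isfinite(v) for v in self.monthly_dt):
            raise ValueError("non-finite temperature deltas")
        if not all(f > 0 for f in self.monthly_sw_factor):
            raise ValueError("shortwave factors must be positive")

    @classmethod
    def uniform(cls, scenario_id: str, dt: float, sw_factor: float = 1.0):
        return cls(scenario_id, (float(dt),) * 12, (float(sw_factor),) * 12)

    @property
    def is_baseline(self) -> bool:
        return all(d == 0.0 for d in self.monthly_dt) and \
            all(f == 1.0 for f in self.monthly_sw_factor)


@dataclass(frozen=True)
class LocationParams:
    """Statistical description of one hydroclimatic setting."""

    location_id: str
    annual_mean: float            # degC
    seasonal_amplitude: float     # degC, half peak-to-trough
    diurnal_range: float = 8.0    # degC (tmax - tmin)
    noise_sd: float = 1.5         # degC, stationary sd of AR(1) anomaly
    ar1: float = 0.7              # lag-1 autocorrelation of daily anomaly
    trough_doy: float = 15.0      # day-of-year of coldest mean temperature
    sw_mean: float = 15.0         # MJ m-2 d-1, annual mean shortwave
    sw_amplitude: float = 8.0     # MJ m-2 d-1, seasonal amplitude
    sw_noise_sd: float = 2.0      # MJ m-2 d-1
    rh_mean: float = 0.70         # mean relative humidity (0-1)
    rh_noise_sd: float = 0.05
    wind_mean: float = 3.0        # m s-1 at 2 m
    wind_noise_sd: float = 0.8
    elevation: float = 0.0        # m
    latitude: float = 40.0        # deg N


@dataclass
class ClimateSeries:
    """Daily meteorological forcing for one location under one scenario."""

    location_id: str
    scenario_id: str
    tmean: np.ndarray             # degC
    tmax: np.ndarray              # degC
    tmin: np.ndarray              # degC
    shortwave: np.ndarray         # MJ m-2 d-1
    specific_humidity: np.ndarray  # kg kg-1
    wind: np.ndarray              # m s-1 at 2 m
    elevation: float = 0.0
    latitude: float = 40.0

    def __post_init__(self):
        n = len(self.tmean)
        for name in ("tmax", "tmin", "shortwave", "specific_humidity", "wind"):
            if len(getattr(self, name)) != n:
                raise ValueError("all daily series must share one length")
        if n % DAYS_PER_YEAR != 0 or n == 0:
            raise ValueError("series length must be a positive multiple of 365")
        if np.any(self.tmin > self.tmean) or np.any(self.tmean > self.tmax):
            raise ValueError("daily temperatures must satisfy tmin <= tmean <= tmax")
        if np.any(self.shortwave < 0) or np.any(self.wind < 0):
            raise ValueError("shortwave and wind must be non-negative")

    @property
    def n_days(self) -> int:
        return len(self.tmean)

    @property
    def n_years(self) -> int:
        return self.n_days // DAYS_PER_YEAR

    @property
    def doy(self) -> np.ndarray:
        """1-based day-of-year for every record (365-day calendar)."""
        return np.tile(np.arange(1, DAYS_PER_YEAR + 1), self.n_years)

    def to_frame(self, start_year: int = 2001) -> pd.DataFrame:
        """Long-format table (ISO dates on the 365-day no-leap calendar)."""
        dates = _noleap_dates(self.n_years, start_year)
        return pd.DataFrame({
            "location_id": self.location_id,
            "scenario_id": self.scenario_id,
            "date": dates,
            "tmean_c": self.tmean,
            "tmax_c": self.tmax,
            "tmin_c": self.tmin,
            "srad_mj_m2": self.shortwave,
            "sh_kg_kg": self.specific_humidity,
            "wind_ms": self.wind,
        })

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, elevation: float = 0.0,
                   latitude: float = 40.0) -> "ClimateSeries":
        return cls(
            location_id=str(frame["location_id"].iloc[0]),
            scenario_id=str(frame["scenario_id"].iloc[0]),
            tmean=frame["tmean_c"].to_numpy(float),
            tmax=frame["tmax_c"].to_numpy(float),
            tmin=frame["tmin_c"].to_numpy(float),
            shortwave=frame["srad_mj_m2"].to_numpy(float),
            specific_humidity=frame["sh_kg_kg"].to_numpy(float),
            wind=frame["wind_ms"].to_numpy(float),
            elevation=elevation, latitude=latitude,
        )


def _noleap_dates(n_years: int, start_year: int):
    month_days = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]
    out = []
    for y in range(n_years):
        year = start_year + y
        for m, nd in enumerate(month_days, start=1):
            for d in range(1, nd + 1):
                out.append(f"{year:04d}-{m:02d}-{d:02d}")
    return out


@dataclass
class ProfileSeries:
    """Daily two-layer thermal state of one simulated lake.

    ``epilimnion`` is the daily maximum temperature of the layer immediately
    above the thermocline (the base of the mixed layer); on mixed days it
    equals ``hypolimnion`` and ``mixed_layer_depth`` equals the lake depth.
    """

    lake_id: str
    location_id: str
    scenario_id: str
    max_depth: float
    epilimnion: np.ndarray
    hypolimnion: np.ndarray
    mixed_layer_depth: np.ndarray
    stratified: np.ndarray

    def __post_init__(self):
        mixed = ~self.stratified
        if np.any(self.mixed_layer_depth <= 0) or \
                np.any(self.mixed_layer_depth > self.max_depth + 1e-9):
            raise ValueError("mixed-layer depth out of (0, max_depth]")
        if np.any(self.epilimnion[mixed] != self.hypolimnion[mixed]):
            raise ValueError("mixed days must have equal layer temperatures")
        if np.any(self.epilimnion < 0) or np.any(self.hypolimnion < 0):
            raise ValueError("temperatures below 0 degC")

    @property
    def n_days(self) -> int:
        return len(self.epilimnion)

    def above_thermocline(self) -> np.ndarray:
        """Daily maximum temperature above the thermocline (bottom layer when mixed)."""
        return np.where(self.stratified, self.epilimnion, self.hypolimnion)

    def vertical_profile(self, day: int, spacing: float = 0.5):
        """Discretize the two-layer state at ``day`` onto a fixed depth grid."""
        depths = np.arange(0.0, self.max_depth + 1e-9, spacing)
        if depths[-1] < self.max_depth:
            depths = np.append(depths, self.max_depth)
        mld = self.mixed_layer_depth[day]
        temps = np.where(depths <= mld, self.epilimnion[day], self.hypolimnion[day])
        return depths, temps


# ---------------------------------------------------------------------------
# climate generation
# ---------------------------------------------------------------------------

def generate_climate(location: LocationParams, delta: ScenarioDelta | None = None,
                     n_years: int = 10, seed: int = 0) -> ClimateSeries:
    """Generate a daily climate series for one location under one scenario.

    Daily mean air temperature is a seasonal cosine (trough at
    ``location.trough_doy``) plus a stationary AR(1) anomaly plus the
    scenario's monthly delta; tmax/tmin bracket the mean by half the diurnal
    range. Shortwave is a seasonal cosine with white noise (scaled by the
    scenario factor); specific humidity follows the delta-applied temperature
    at the location's mean relative humidity; wind is white noise about the
    location mean. A fixed ``seed`` gives a bit-identical series, and because
    the weather noise depends only on ``(location, n_years, seed)``, scenarios
    that share a seed differ from the baseline exactly by their change signal.
    """
    if delta is None:
        delta = ScenarioDelta("baseline")
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    p = location
    for v in (p.annual_mean, p.seasonal_amplitude, p.diurnal_range, p.noise_sd):
        if not math.isfinite(v):
            raise ValueError("non-finite location parameters")
    if p.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    n = n_years * DAYS_PER_YEAR
    doy = np.tile(np.arange(1, DAYS_PER_YEAR + 1), n_years)
    month = np.tile(_MONTH_OF_DOY, n_years)
    phase = 2.0 * np.pi * (doy - p.trough_doy) / DAYS_PER_YEAR

    # AR(1) anomaly with stationary sd = noise_sd
    anom = np.zeros(n)
    if p.noise_sd > 0:
        innov_sd = p.noise_sd * math.sqrt(max(1.0 - p.ar1 ** 2, 1e-12))
        eps = rng.normal(0.0, 1.0, size=n)
        anom[0] = p.noise_sd * eps[0]
        for t in range(1, n):
            anom[t] = p.ar1 * anom[t - 1] + innov_sd * eps[t]
    else:
        rng.normal(0.0, 1.0, size=n)  # keep the stream position scenario-independent

    dt_monthly = np.asarray(delta.monthly_dt, dtype=float)[month]
    tmean = p.annual_mean - p.seasonal_amplitude * np.cos(phase) + anom + dt_monthly
    tmax = tmean + p.diurnal_range / 2.0
    tmin = tmean - p.diurnal_range / 2.0

    sw = (p.sw_mean - p.sw_amplitude * np.cos(phase)
          + rng.normal(0.0, p.sw_noise_sd, size=n))
    sw = np.clip(sw, 0.3, None) * np.asarray(delta.monthly_sw_factor)[month]

    # humidity follows the *baseline* temperature: warming scenarios keep
    # absolute humidity near historical levels (falling relative humidity),
    # the warm-dry regime under which lake thermal risk is largest
    rh = np.clip(rng.normal(p.rh_mean, p.rh_noise_sd, size=n), 0.2, 1.0)
    pressure = surface_pressure(p.elevation)
    ea = rh * saturation_vapor_pressure(tmean - dt_monthly)
    q = 0.622 * ea / (pressure - 0.378 * ea)

    wind = np.clip(rng.normal(p.wind_mean, p.wind_noise_sd, size=n), 0.1, None)

    return ClimateSeries(
        location_id=p.location_id, scenario_id=delta.scenario_id,
        tmean=tmean, tmax=tmax, tmin=tmin, shortwave=sw,
        specific_humidity=q, wind=wind,
        elevation=p.elevation, latitude=p.latitude,
    )


# ---------------------------------------------------------------------------
# two-layer lake simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatorParams:
    """Frozen coefficient set of the two-layer energy balance.

    The named ``default`` set was calibrated once against the qualitative
    response-surface structure (warming response declining with baseline
    summer air temperature; possible cooling of the above-thermocline maximum
    in small, deep, clear lakes) and is never adjusted afterwards.
    """

    name: str = "default"
    solar_gain: float = 0.24        # degC per MJ m-2 d-1 absorbed in the mixed layer
    evap_coeff: float = 1.2         # degC per (m s-1 * kPa) of wind * water VPD
    mld_clarity: float = 1.75       # m per (m^-1)^-1: clarity term c1/extinction
    mld_fetch: float = 0.57         # m per fetch^0.25 (fetch in m)
    mld_stability: float = 0.38     # m shoaling per degC of (epi - hypo)
    relax_rate: float = 0.87        # m d-1; epilimnion rate = relax_rate / mld
    hypo_rate: float = 0.009        # m d-1; hypolimnion rate = hypo_rate / hypo thickness
    shield: float = 1.95            # metalimnetic shading strength (dimensionless)
    shield_fetch: float = 575.0     # m; shading e-folding scale in fetch
    shield_depth: float = 15.5      # m; depth below which shading tapers linearly
    strat_threshold: float = 1.0    # degC of (epi - hypo) defining stratification
    ice_attenuation: float = 0.05   # exchange-rate multiplier while air < 0 degC
    spinup_days: int = DAYS_PER_YEAR


DEFAULT_SIMULATOR = SimulatorParams()

#: named parameter sets, addressable from the pipeline config
SIMULATOR_PARAM_SETS = {"default": DEFAULT_SIMULATOR}


def simulate_lake(lake: LakeConfig, climate: ClimateSeries,
                  params: SimulatorParams = DEFAULT_SIMULATOR) -> ProfileSeries:
    """Integrate the daily two-layer energy balance of one lake.

    The epilimnion relaxes toward an equilibrium temperature

        E = T_air + a * SW * (1 - exp(-eta * z_mix)) - b * u * max(e_s(T_epi) - e_a, 0)

    with rate ``relax_rate / z_mix`` per day, where the mixed-layer depth is

        z_mix = clip(c1 / eta + c2 * fetch^0.25 - c3 * max(T_epi - T_hypo, 0), 1, H)

    The hypolimnion relaxes slowly toward the epilimnion while stratified,
    the column mixes fully (volume-weighted mean) whenever the epilimnion is
    no warmer than the hypolimnion, water temperature is floored at 0 degC,
    and surface exchange is attenuated while air temperature is below 0 degC
    (ice cap). The reported above-thermocline temperature subtracts a
    metalimnetic shading term

        shield * (T_epi - T_hypo) * exp(-eta * z_mix)
               * exp(-fetch / shield_fetch) * min(H / shield_depth, 1)

    representing the cool gradient zone at the base of the mixed layer that
    develops in small (wind-sheltered), deep, clear lakes -- the regime in
    which stronger stratification under warming can lower the
    above-thermocline maximum.

    The first year of forcing is run once as spin-up and discarded.
    """
    if climate.n_years < 1:
        raise ValueError("climate must cover at least one whole year")
    if lake.extinction <= 0:
        raise ValueError("extinction must be positive")

    depth = lake.max_depth
    ext = lake.extinction
    fetch_term = params.mld_fetch * lake.fetch ** 0.25
    clarity_term = params.mld_clarity / ext
    shield_w = (params.shield * math.exp(-lake.fetch / params.shield_fetch)
                * min(depth / params.shield_depth, 1.0))
    pressure = surface_pressure(climate.elevation)

    tair = climate.tmean
    sw = climate.shortwave
    wind = climate.wind
    ea_all = vapor_pressure_from_specific_humidity(climate.specific_humidity, pressure)

    n = climate.n_days
    spin = min(params.spinup_days, n)
    order = list(range(spin)) + list(range(n))

    epi = max(float(np.mean(tair[:DAYS_PER_YEAR])), 4.0)
    hypo = epi
    out_epi = np.empty(n)
    out_hypo = np.empty(n)
    out_mld = np.empty(n)
    out_strat = np.empty(n, dtype=bool)

    ta = tair.tolist()
    swl = sw.tolist()
    wl = wind.tolist()
    eal = ea_all.tolist()

    pos = 0
    for step, d in enumerate(order):
        stability = epi - hypo if epi > hypo else 0.0
        mld = clarity_term + fetch_term - params.mld_stability * stability
        if mld < 1.0:
            mld = 1.0
        elif mld > depth:
            mld = depth

        capture = 1.0 - math.exp(-ext * mld)
        es_water = 0.6108 * math.exp(17.27 * epi / (epi + 237.3))
        vpd = es_water - eal[d]
        if vpd < 0.0:
            vpd = 0.0
        equil = (ta[d] + params.solar_gain * swl[d] * capture
                 - params.evap_coeff * wl[d] * vpd)

        rate = params.relax_rate / mld
        if rate > 0.9:
            rate = 0.9
        hypo_thick = depth - mld
        h_rate = params.hypo_rate / hypo_thick if hypo_thick > 1.0 else params.hypo_rate
        if h_rate > 0.9:
            h_rate = 0.9
        if ta[d] < 0.0:  # ice cap attenuates exchange
            rate *= params.ice_attenuation
            h_rate *= params.ice_attenuation

        epi = epi + rate * (equil - epi)
        if epi - hypo > 0.0:
            hypo = hypo + h_rate * (epi - hypo)

        if epi <= hypo:  # turnover: full volume-weighted mixing
            w_epi = mld / depth
            mixed_t = w_epi * epi + (1.0 - w_epi) * hypo
            epi = hypo = mixed_t

        if epi < 0.0:
            epi = 0.0
        if hypo < 0.0:
            hypo = 0.0

        if step >= spin:
            stratified = (epi - hypo) > params.strat_threshold
            if stratified:
                shade = shield_w * (epi - hypo) * math.exp(-ext * mld)
                top = epi - shade
                if top < hypo:
                    top = hypo
                out_epi[pos] = top
                out_hypo[pos] = hypo
                out_mld[pos] = mld
            else:
                w_epi = mld / depth
                mixed_t = w_epi * epi + (1.0 - w_epi) * hypo
                out_epi[pos] = mixed_t
                out_hypo[pos] = mixed_t
                out_mld[pos] = depth
            out_strat[pos] = stratified
            pos += 1

    return ProfileSeries(
        lake_id=lake.lake_id, location_id=climate.location_id,
        scenario_id=climate.scenario_id, max_depth=depth,
        epilimnion=out_epi, hypolimnion=out_hypo,
        mixed_layer_depth=out_mld, stratified=out_strat,
    )


# ---------------------------------------------------------------------------
# synthetic lake table
# ---------------------------------------------------------------------------

def generate_lake_table(n: int, depth_range=DEPTH_RANGE, area_range=AREA_RANGE,
                        extinction_range=EXTINCTION_RANGE,
                        latitude_range=(28.0, 48.0), seed: int = 0):
    """Random synthetic lake population mirroring a national survey sample.

    Areas are log-uniform on ``area_range`` (m^2), depths uniform on
    ``depth_range`` (m), extinction log-uniform on ``extinction_range``
    (m^-1), latitudes uniform (used only to assign lakes to climate
    locations). Ranges outside the training envelope are allowed but warned
    about, since the surrogate would then extrapolate.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if depth_range[0] < DEPTH_RANGE[0] or depth_range[1] > DEPTH_RANGE[1] or \
            area_range[0] < AREA_RANGE[0] or area_range[1] > AREA_RANGE[1]:
        warnings.warn("lake table ranges extend beyond the training envelope; "
                      "surrogate predictions there are extrapolations",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    depths = rng.uniform(depth_range[0], depth_range[1], size=n)
    areas = np.exp(rng.uniform(math.log(area_range[0]), math.log(area_range[1]), size=n))
    exts = np.exp(rng.uniform(math.log(extinction_range[0]),
                              math.log(extinction_range[1]), size=n))
    lats = rng.uniform(latitude_range[0], latitude_range[1], size=n)
    return [
        LakeConfig(lake_id=f"lake{i + 1:04d}", max_depth=float(depths[i]),
                   surface_area=float(areas[i]), extinction=float(exts[i]),
                   latitude=float(lats[i]))
        for i in range(n)
    ]


def lake_table_to_frame(lakes) -> pd.DataFrame:
    return pd.DataFrame({
        "lake_id": [lk.lake_id for lk in lakes],
        "max_depth_m": [lk.max_depth for lk in lakes],
        "surface_area_m2": [lk.surface_area for lk in lakes],
        "extinction_m1": [lk.extinction for lk in lakes],
        "elevation_m": [lk.elevation for lk in lakes],
        "latitude_deg": [lk.latitude for lk in lakes],
    })


def lake_table_from_frame(frame: pd.DataFrame):
    return [
        LakeConfig(lake_id=str(r.lake_id), max_depth=float(r.max_depth_m),
                   surface_area=float(r.surface_area_m2),
                   extinction=float(r.extinction_m1),
                   elevation=float(r.elevation_m), latitude=float(r.latitude_deg))
        for r in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# named presets
# ---------------------------------------------------------------------------

#: hydroclimatic location presets spanning humid sub-tropical to cold
#: high-elevation settings (annual means 22.3 degC down to 4.6 degC)
LOCATION_PRESETS = {
    "subtropical": LocationParams(
        "subtropical", annual_mean=22.3, seasonal_amplitude=6.5, diurnal_range=9.0,
        sw_mean=16.5, sw_amplitude=6.5, rh_mean=0.73, wind_mean=3.4,
        elevation=10.0, latitude=28.0),
    "continental": LocationParams(
        "continental", annual_mean=10.0, seasonal_amplitude=14.0, diurnal_range=10.0,
        sw_mean=14.5, sw_amplitude=8.5, rh_mean=0.70, wind_mean=3.0,
        elevation=250.0, latitude=41.0),
    "alpine": LocationParams(
        "alpine", annual_mean=4.6, seasonal_amplitude=11.5, diurnal_range=12.0,
        sw_mean=16.0, sw_amplitude=9.0, rh_mean=0.62, wind_mean=3.0,
        elevation=2900.0, latitude=39.0),
    "maritime": LocationParams(
        "maritime", annual_mean=11.5, seasonal_amplitude=6.0, diurnal_range=7.0,
        sw_mean=13.0, sw_amplitude=7.5, rh_mean=0.78, wind_mean=4.0,
        elevation=50.0, latitude=46.0),
    "semiarid": LocationParams(
        "semiarid", annual_mean=14.0, seasonal_amplitude=11.0, diurnal_range=14.0,
        sw_mean=18.5, sw_amplitude=8.0, rh_mean=0.45, wind_mean=4.0,
        elevation=1300.0, latitude=35.0),
    "humid_temperate": LocationParams(
        "humid_temperate", annual_mean=13.0, seasonal_amplitude=11.0, diurnal_range=9.0,
        sw_mean=14.0, sw_amplitude=7.5, rh_mean=0.72, wind_mean=3.0,
        elevation=150.0, latitude=36.5),
    "northern": LocationParams(
        "northern", annual_mean=6.5, seasonal_amplitude=16.0, diurnal_range=10.0,
        sw_mean=13.5, sw_amplitude=9.0, rh_mean=0.70, wind_mean=3.5,
        elevation=400.0, latitude=47.0),
    "gulf": LocationParams(
        "gulf", annual_mean=19.5, seasonal_amplitude=8.0, diurnal_range=9.5,
        sw_mean=16.5, sw_amplitude=6.5, rh_mean=0.74, wind_mean=3.2,
        elevation=30.0, latitude=31.0),
    "interior_west": LocationParams(
        "interior_west", annual_mean=8.5, seasonal_amplitude=12.5, diurnal_range=14.0,
        sw_mean=17.5, sw_amplitude=8.5, rh_mean=0.50, wind_mean=3.8,
        elevation=1600.0, latitude=43.0),
}

#: training scenario presets: historical baseline plus warming of
#: increasing magnitude, with a mild winter emphasis in the monthly pattern
def _seasonal_delta(scenario_id: str, mean_dt: float) -> ScenarioDelta:
    # winter months warm slightly faster than summer, as in downscaled GCM output
    pattern = np.array([1.2, 1.2, 1.1, 1.0, 0.9, 0.85, 0.85, 0.9, 1.0, 1.05, 1.1, 1.15])
    dts = mean_dt * pattern / pattern.mean()
    return ScenarioDelta(scenario_id, tuple(float(x) for x in dts))


SCENARIO_PRESETS = {
    "baseline": ScenarioDelta("baseline"),
    "warm_low": _seasonal_delta("warm_low", 2.0),
    "warm_mid": _seasonal_delta("warm_mid", 4.0),
    "warm_high": _seasonal_delta("warm_high", 6.0),
    "warm_1": _seasonal_delta("warm_1", 1.5),
    "warm_3": _seasonal_delta("warm_3", 3.0),
    "warm_5": _seasonal_delta("warm_5", 5.0),
}

#: projection ensemble members: late-century warming spread across members,
#: mirroring the 3.1-7.1 degC spread of annual-mean warming across GCMs
ENSEMBLE_LATE_CENTURY = [
    _seasonal_delta("member_1", 3.1),
    _seasonal_delta("member_2", 3.9),
    _seasonal_delta("member_3", 4.6),
    _seasonal_delta("member_4", 5.3),
    _seasonal_delta("member_5", 6.2),
    _seasonal_delta("member_6", 7.1),
]

#: mid-century members at roughly 60% of the late-century signal
ENSEMBLE_MID_CENTURY = [
    replace(m, scenario_id=m.scenario_id,
            monthly_dt=tuple(0.6 * d for d in m.monthly_dt))
    for m in ENSEMBLE_LATE_CENTURY
]

#: frozen fixture presets for the decrease-prone regime: small, deep, clear
#: lakes (geometry ratio well below 10)
FIXTURE_DECREASE_LAKES = [
    LakeConfig("fixture_deep_clear_small", max_depth=28.0, surface_area=1.5e5,
               extinction=0.2),
    LakeConfig("fixture_deep_clear_mid", max_depth=24.0, surface_area=4e5,
               extinction=0.25),
    LakeConfig("fixture_deep_moderate", max_depth=30.0, surface_area=2.5e5,
               extinction=0.3),
]
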