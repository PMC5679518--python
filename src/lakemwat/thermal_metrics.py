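"""Thermal-stress metrics: thermocline detection and MWAT (7DADMax).

MWAT -- the maximum weekly average temperature -- is the highest annual
average of seven consecutive daily maximum temperatures, the standard
chronic thermal-stress index for fish. Here it is evaluated on the daily
maximum temperature of the layer immediately above the thermocline during
stratification (or of the bottom layer during mixed conditions), the
habitat-relevant depth for cold-water species seeking refuge near the
bottom of the oxygenated mixed zone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_lake import DAYS_PER_YEAR, ProfileSeries

#: interfaces shallower than this depth (m) are ignored when locating the
#: thermocline, excluding transient near-surface (diurnal) gradients
SURFACE_EXCLUSION_M = 1.0

#: default vertical gradient (degC per m) separating stratified from mixed
STRATIFICATION_THRESHOLD = 1.0


def detect_thermocline(profile, stratification_threshold: float = STRATIFICATION_THRESHOLD):
    """Locate the thermocline in one vertical profile.

    Parameters
    ----------
    profile
        Sequence of ``(depth_m, temp_c)`` pairs, depths strictly increasing
        from the surface down.
    stratification_threshold
        Minimum absolute adjacent-layer gradient (degC/m) for the water
        column to count as stratified.

    Returns
    -------
    (stratified, layer_index_above)
        ``layer_index_above`` indexes the layer immediately above the
        interface of maximum |dT|/dz among interfaces deeper than 1 m; when
        no gradient reaches the threshold the column is mixed and the bottom
        layer is returned. Ties go to the shallowest qualifying interface.
    """
    profile = [(float(d), float(t)) for d, t in profile]
    if len(profile) < 2:
        raise ValueError("need at least two layers")
    depths = np.array([d for d, _ in profile])
    temps = np.array([t for _, t in profile])
    if np.any(np.diff(depths) <= 0):
        raise ValueError("depths must be strictly increasing")

    grads = np.abs(np.diff(temps)) / np.diff(depths)
    deeper_than_surface = depths[1:] > SURFACE_EXCLUSION_M
    best_idx, best_grad = None, -np.inf
    for i in range(len(grads)):
        if deeper_than_surface[i] and grads[i] > best_grad:
            best_idx, best_grad = i, grads[i]
    if best_idx is None or best_grad < stratification_threshold:
        return False, len(profile) - 1
    return True, best_idx


def rolling_7day_mean(series) -> np.ndarray:
    """Trailing 7-day means; element t covers days t-6..t (first 6 omitted)."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or len(series) < 7:
        raise ValueError("need a 1-D series of at least 7 values")
    return np.convolve(series, np.full(7, 1.0 / 7.0), mode="valid")


@dataclass
class MWATResult:
    """Per-year and aggregate MWAT for one lake/run."""

    annual: np.ndarray        # degC, one MWAT per simulated year
    aggregate: float          # degC
    window_starts: np.ndarray  # 0-based day-of-year of each year's peak window
    aggregate_mode: str = "mean"


def mwat(daily, aggregate_mode: str = "mean") -> MWATResult:
    """MWAT from a daily above-thermocline maximum-temperature series.

    The series must span whole 365-day years; the 7-day windows never cross
    year boundaries ("highest annual average"). Annual MWATs are reduced to
    one aggregate by their mean (default) or maximum.
    """
    daily = np.asarray(daily, dtype=float)
    if daily.ndim != 1 or len(daily) == 0 or len(daily) % DAYS_PER_YEAR != 0:
        raise ValueError("daily series must span whole 365-day years")
    if aggregate_mode not in ("mean", "max"):
        raise ValueError("aggregate_mode must be 'mean' or 'max'")
    n_years = len(daily) // DAYS_PER_YEAR
    annual = np.empty(n_years)
    starts = np.empty(n_years, dtype=int)
    for y in range(n_years):
        year = daily[y * DAYS_PER_YEAR:(y + 1) * DAYS_PER_YEAR]
        weekly = rolling_7day_mean(year)
        k = int(np.argmax(weekly))
        annual[y] = weekly[k]
        starts[y] = k
    agg = float(annual.mean() if aggregate_mode == "mean" else annual.max())
    return MWATResult(annual=annual, aggregate=agg, window_starts=starts,
                      aggregate_mode=aggregate_mode)


def mwat_from_profile(profile: ProfileSeries, aggregate_mode: str = "mean") -> MWATResult:
    """MWAT of the daily above-thermocline temperature of a simulated lake."""
    return mwat(profile.above_thermocline(), aggregate_mode=aggregate_mode)


def daily_above_thermocline_from_grid(depth_grid_series, threshold_c_per_m: float = STRATIFICATION_THRESHOLD):
    """Daily above-thermocline temperatures from discretized vertical profiles.

    ``depth_grid_series`` is an iterable of per-day ``(depths, temps)``
    arrays; each day is classified with :func:`detect_thermocline` and the
    temperature of the selected layer is returned.
    """
    out = []
    for depths, temps in depth_grid_series:
        _, idx = detect_thermocline(list(zip(depths, temps)), threshold_c_per_m)
        out.append(float(temps[idx]))
    return np.asarray(out)
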