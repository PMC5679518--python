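"""Applying the trained surrogate to a lake population under climate
scenario ensembles: per-lake MWAT change, exceedance fractions, empirical
distributions and 95% confidence limits.

The headline analysis uses the elementwise median monthly air-temperature
and PET series across ensemble members (the "median" mode); a per-member
mode exposes the spread across members. Confidence limits are the GP's own
95% predictive limits; cross-member range is reported separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gp_surrogate import TrainedGP, predict
from .predictors import FEATURES_DEFAULT, FeatureVector, geometry_ratio
from .synthetic_lake import ClimateSeries, LakeConfig, lake_table_from_frame

logger = logging.getLogger(__name__)

#: approximate chronic-stress threshold (degC) for cold-water fisheries
EXCEEDANCE_THRESHOLD = 30.0

MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


def monthly_series_from_climate(climate: ClimateSeries,
                                member_id: str | None = None) -> pd.DataFrame:
    """Reduce a daily climate series to mean monthly air temperature and
    monthly PET totals (averaged across years)."""
    from .predictors import pet_fao56_daily  # local import avoids cycle at startup

    doy = climate.doy
    month = np.searchsorted(np.cumsum(MONTH_DAYS), doy - 1, side="right") + 1
    et0 = pet_fao56_daily(climate.tmax, climate.tmin, climate.specific_humidity,
                          climate.shortwave, climate.wind,
                          climate.elevation, climate.latitude, doy)
    frame = pd.DataFrame({"month": month, "t_air_c": climate.tmean, "pet_mm": et0})
    monthly = frame.groupby("month").agg(t_air_c=("t_air_c", "mean"),
                                         pet_mm=("pet_mm", "sum")).reset_index()
    monthly["pet_mm"] /= climate.n_years
    monthly.insert(0, "location_id", climate.location_id)
    monthly.insert(0, "member_id",
                   member_id if member_id is not None else climate.scenario_id)
    monthly["latitude"] = climate.latitude
    return monthly


def ensemble_median_series(ensemble: pd.DataFrame) -> pd.DataFrame:
    """Elementwise median across members for every (location, month).

    With an even member count the median is the mean of the central pair.
    Members must cover identical (location, month) grids.
    """
    if ensemble.empty:
        raise ValueError("ensemble must have at least one member")
    counts = ensemble.groupby("member_id").size()
    if counts.nunique() != 1:
        raise ValueError("ragged ensemble: members cover different grids")
    med = (ensemble.groupby(["location_id", "month"])
           .agg(t_air_c=("t_air_c", "median"), pet_mm=("pet_mm", "median"),
                latitude=("latitude", "first"))
           .reset_index())
    med.insert(0, "member_id", "median")
    return med


def features_from_monthly(lake: LakeConfig, monthly: pd.DataFrame) -> FeatureVector:
    """Predictor vector from one location's 12-month series."""
    m = monthly.set_index("month")
    t_ja = float((m.loc[7, "t_air_c"] * 31 + m.loc[8, "t_air_c"] * 31) / 62.0)
    return FeatureVector(
        t_july_aug=t_ja,
        t_jan=float(m.loc[1, "t_air_c"]),
        pet=float(m["pet_mm"].sum()),
        extinction=lake.extinction,
        geometry_ratio=geometry_ratio(lake.surface_area, lake.max_depth),
        max_depth=lake.max_depth, surface_area=lake.surface_area,
    )


@dataclass
class LakeProjection:
    """Baseline and future MWAT of one lake with GP uncertainty."""

    lake_id: str
    location_id: str
    mwat_baseline: float   # degC
    mwat_future: float     # degC
    delta: float           # degC, future - baseline
    sd_future: float       # degC, GP predictive sd
    lower95: float         # degC
    upper95: float         # degC
    extrapolated: bool = False
    member_mwats: dict = field(default_factory=dict)


def _nearest_location(lake: LakeConfig, loc_lat: pd.Series) -> str:
    return str((loc_lat - lake.latitude).abs().idxmin())


def project_lakes(gp: TrainedGP, lakes, baseline: pd.DataFrame,
                  ensemble: pd.DataFrame, mode: str = "median"):
    """Project baseline and future MWAT for every lake in a table.

    Parameters
    ----------
    gp
        Trained surrogate; its ``feature_names`` select the predictors.
    lakes
        List of :class:`LakeConfig` or a lake-table DataFrame (rows with
        missing characteristics are dropped with a logged count).
    baseline, ensemble
        Monthly-series frames (``member_id, location_id, month, t_air_c,
        pet_mm, latitude``); the baseline may hold one member. Lakes are
        assigned to the nearest location by latitude.
    mode
        ``"median"`` predicts from the cross-member median series (the
        headline mode); ``"per_member"`` additionally records member-wise
        MWAT predictions.

    Returns a list of :class:`LakeProjection`.
    """
    if mode not in ("median", "per_member"):
        raise ValueError("mode must be 'median' or 'per_member'")
    if isinstance(lakes, pd.DataFrame):
        n0 = len(lakes)
        lakes = lakes.dropna()
        if len(lakes) < n0:
            logger.info("dropped %d lakes with incomplete morphometric data",
                        n0 - len(lakes))
        lakes = lake_table_from_frame(lakes)

    names = gp.feature_names or FEATURES_DEFAULT
    base_med = ensemble_median_series(baseline)
    fut_med = ensemble_median_series(ensemble)
    loc_lat = base_med.groupby("location_id")["latitude"].first()
    members = sorted(ensemble["member_id"].unique())

    lo = gp.features.min(axis=0)
    hi = gp.features.max(axis=0)

    out = []
    for lake in lakes:
        loc = _nearest_location(lake, loc_lat)
        fv_base = features_from_monthly(lake, base_med[base_med.location_id == loc])
        fv_fut = features_from_monthly(lake, fut_med[fut_med.location_id == loc])
        xb = fv_base.to_array(names)
        xf = fv_fut.to_array(names)
        pb = predict(gp, xb)
        pf = predict(gp, xf)
        xs = gp.standardize(np.vstack([xb, xf]))
        extrap = bool(np.any(xs < lo - 1e-9) or np.any(xs > hi + 1e-9))
        member_mwats = {}
        if mode == "per_member":
            for mem in members:
                sub = ensemble[ensemble.member_id == mem]
                fv_m = features_from_monthly(lake, sub[sub.location_id == loc])
                member_mwats[mem] = float(predict(gp, fv_m.to_array(names)).mean)
        out.append(LakeProjection(
            lake_id=lake.lake_id, location_id=loc,
            mwat_baseline=float(pb.mean), mwat_future=float(pf.mean),
            delta=float(pf.mean - pb.mean), sd_future=float(pf.sd),
            lower95=float(pf.lower95), upper95=float(pf.upper95),
            extrapolated=extrap, member_mwats=member_mwats,
        ))
    return out


def projections_to_frame(projections) -> pd.DataFrame:
    rows = []
    for p in projections:
        row = {"lake_id": p.lake_id, "location_id": p.location_id,
               "mwat_baseline_c": p.mwat_baseline, "mwat_future_c": p.mwat_future,
               "delta_c": p.delta, "sd_future_c": p.sd_future,
               "lower95_c": p.lower95, "upper95_c": p.upper95,
               "extrapolated": p.extrapolated}
        for mem, v in p.member_mwats.items():
            row[f"mwat_{mem}_c"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def _field_values(projections, field_name: str) -> np.ndarray:
    attr = {"baseline": "mwat_baseline", "future": "mwat_future",
            "delta": "delta"}[field_name]
    return np.array([getattr(p, attr) for p in projections])


def exceedance_fraction(projections, threshold: float = EXCEEDANCE_THRESHOLD,
                        field: str = "future") -> float:
    """Percentage of lakes with MWAT strictly exceeding ``threshold``."""
    if not projections:
        raise ValueError("no projections")
    vals = _field_values(projections, field)
    return 100.0 * float((vals > threshold).sum()) / len(vals)


def mwat_cdf(projections, field: str = "future") -> pd.DataFrame:
    """Empirical cumulative distribution of MWAT across the cohort."""
    if not projections:
        raise ValueError("no projections")
    vals = np.sort(_field_values(projections, field))
    frac = np.arange(1, len(vals) + 1) / len(vals)
    return pd.DataFrame({"mwat_c": vals, "cumulative_fraction": frac})


@dataclass
class DecreaserSummary:
    """Lakes with a projected MWAT decline and their geometry-ratio spread."""

    percent: float
    n: int
    gr_min: float | None = None
    gr_median: float | None = None
    gr_max: float | None = None


def summarize_decreasers(projections, lakes) -> DecreaserSummary:
    """Fraction of lakes with delta < 0 and the geometry-ratio distribution
    of that subset (empty summary when no lake declines)."""
    gr_by_id = {lk.lake_id: geometry_ratio(lk.surface_area, lk.max_depth)
                for lk in lakes}
    deltas = np.array([p.delta for p in projections])
    dec = [p for p in projections if p.delta < 0]
    pct = 100.0 * len(dec) / len(projections)
    if not dec:
        return DecreaserSummary(percent=pct, n=0)
    grs = np.array([gr_by_id[p.lake_id] for p in dec])
    return DecreaserSummary(percent=pct, n=len(dec),
                            gr_min=float(grs.min()),
                            gr_median=float(np.median(grs)),
                            gr_max=float(grs.max()))
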