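"""Heatwave detection and daytime/nighttime heatwave indices (HWIs).

A heatwave is a run of at least ``min_duration`` consecutive warm-season days
on which daily maximum (Tmax) or minimum (Tmin) temperature strictly exceeds
its local climatological percentile threshold (default: 95th percentile of
May-October days over a 30-year reference period). Each event is classified as
*daytime-accentuated* when the cumulative excess of Tmax over its threshold
during the event is larger than the cumulative excess of Tmin, and
*nighttime-accentuated* otherwise. On heatwave days the daytime HWI is the
excess of Tmax over its threshold and the nighttime HWI is the excess of Tmin
over its threshold (both in degrees C, floored at zero); on non-heatwave days
both indices are zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_SEASON_MONTHS: tuple[int, ...] = (5, 6, 7, 8, 9, 10)

DAYTIME = "daytime_accentuated"
NIGHTTIME = "nighttime_accentuated"


@dataclass(frozen=True)
class ThresholdSet:
    """Per-location Tmax/Tmin percentile thresholds.

    ``values`` is indexed by ``location_id`` with columns ``tmax_threshold``
    and ``tmin_threshold`` (degrees C).
    """

    values: pd.DataFrame
    percentile_level: float = 0.95
    reference_period: tuple[int, int] = (1981, 2010)
    season_months: tuple[int, ...] = DEFAULT_SEASON_MONTHS

    def __post_init__(self) -> None:
        if not 0.0 < self.percentile_level < 1.0:
            raise ValueError("percentile_level must lie in (0, 1)")
        missing = {"tmax_threshold", "tmin_threshold"} - set(self.values.columns)
        if missing:
            raise ValueError(f"threshold table lacks columns: {sorted(missing)}")
        if not np.isfinite(self.values[["tmax_threshold", "tmin_threshold"]]).all().all():
            raise ValueError("thresholds must be finite")

    def for_location(self, location_id) -> tuple[float, float]:
        row = self.values.loc[location_id]
        return float(row["tmax_threshold"]), float(row["tmin_threshold"])

    @property
    def locations(self) -> pd.Index:
        return self.values.index


def _season_mask(dates: pd.Series, season_months) -> pd.Series:
    return dates.dt.month.isin(set(season_months))


def _as_climate(climate: pd.DataFrame) -> pd.DataFrame:
    clim = climate.copy()
    clim["date"] = pd.to_datetime(clim["date"])
    return clim


def compute_thresholds(
    climate: pd.DataFrame,
    percentile_level: float = 0.95,
    reference_period: tuple[int, int] = (1981, 2010),
    season_months=DEFAULT_SEASON_MONTHS,
) -> ThresholdSet:
    """Pooled warm-season percentile thresholds per location.

    The percentile pools every season-month day of every reference year (no
    day-of-year window) and interpolates linearly between the closest order
    statistics, i.e. position h = (n-1)p + 1 (the numpy/R type-7 default).

    Raises ``ValueError`` naming any location present in ``climate`` that has
    no valid season day inside the reference period.
    """
    clim = _as_climate(climate)
    y0, y1 = reference_period
    year = clim["date"].dt.year
    ref = clim[_season_mask(clim["date"], season_months) & year.between(y0, y1)]
    all_locs = pd.Index(clim["location_id"].unique())
    have = pd.Index(ref["location_id"].unique())
    missing = all_locs.difference(have)
    if len(missing) > 0:
        raise ValueError(
            "no reference-period season days for location(s): "
            + ", ".join(map(str, missing[:10]))
        )
    vals = (
        ref.groupby("location_id")[["tmax", "tmin"]]
        .quantile(percentile_level)
        .rename(columns={"tmax": "tmax_threshold", "tmin": "tmin_threshold"})
    )
    return ThresholdSet(
        values=vals,
        percentile_level=percentile_level,
        reference_period=reference_period,
        season_months=tuple(season_months),
    )


def _join_thresholds(clim: pd.DataFrame, thresholds: ThresholdSet) -> pd.DataFrame:
    locs = pd.Index(clim["location_id"].unique())
    missing = locs.difference(thresholds.locations)
    if len(missing) > 0:
        raise ValueError(
            "no thresholds for location(s): " + ", ".join(map(str, missing[:10]))
        )
    return clim.merge(
        thresholds.values, left_on="location_id", right_index=True, how="left"
    )


def detect_heatwave_events(
    climate: pd.DataFrame,
    thresholds: ThresholdSet,
    min_duration: int = 2,
) -> pd.DataFrame:
    """Maximal runs of consecutive season days exceeding either threshold.

    A day qualifies when tmax > tmax_threshold OR tmin > tmin_threshold
    (strict). Runs never span a calendar gap (missing day), a non-season
    month, or a year boundary; days with missing tmax or tmin never qualify
    and therefore break runs. Runs shorter than ``min_duration`` are dropped.

    Returns a frame with one row per event: location_id, start_date, end_date,
    duration, cum_excess_tmax, cum_excess_tmin, event_type. Classification is
    daytime-accentuated iff cum_excess_tmax > cum_excess_tmin (ties go to
    nighttime-accentuated, a deterministic rule for measure-zero ties).
    """
    if min_duration < 1:
        raise ValueError("min_duration must be >= 1")
    clim = _as_climate(climate)
    clim = clim[_season_mask(clim["date"], thresholds.season_months)]
    clim = clim.sort_values(["location_id", "date"]).reset_index(drop=True)
    if clim.duplicated(["location_id", "date"]).any():
        raise ValueError("duplicate location-day rows in climate input")
    df = _join_thresholds(clim, thresholds)

    valid = df["tmax"].notna() & df["tmin"].notna()
    exceed = valid & (
        (df["tmax"] > df["tmax_threshold"]) | (df["tmin"] > df["tmin_threshold"])
    )
    same_loc = df["location_id"].eq(df["location_id"].shift())
    consecutive = df["date"].diff().dt.days.eq(1)
    same_year = df["date"].dt.year.eq(df["date"].dt.year.shift())
    chained = exceed.shift(fill_value=False) & same_loc & consecutive & same_year
    run_id = (exceed & ~chained).cumsum()

    days = df[exceed].copy()
    if days.empty:
        return pd.DataFrame(
            columns=[
                "location_id", "start_date", "end_date", "duration",
                "cum_excess_tmax", "cum_excess_tmin", "event_type",
            ]
        )
    days["excess_tmax"] = (days["tmax"] - days["tmax_threshold"]).clip(lower=0.0)
    days["excess_tmin"] = (days["tmin"] - days["tmin_threshold"]).clip(lower=0.0)
    ev = (
        days.groupby(run_id[exceed])
        .agg(
            location_id=("location_id", "first"),
            start_date=("date", "min"),
            end_date=("date", "max"),
            duration=("date", "size"),
            cum_excess_tmax=("excess_tmax", "sum"),
            cum_excess_tmin=("excess_tmin", "sum"),
        )
        .reset_index(drop=True)
    )
    ev = ev[ev["duration"] >= min_duration].reset_index(drop=True)
    ev["event_type"] = np.where(
        ev["cum_excess_tmax"] > ev["cum_excess_tmin"], DAYTIME, NIGHTTIME
    )
    return ev


def _explode_event_days(events: pd.DataFrame) -> pd.DataFrame:
    if events.empty:
        return pd.DataFrame(columns=["location_id", "date", "event_type"])
    rows = []
    for loc, start, end, etype in zip(
        events["location_id"], events["start_date"], events["end_date"],
        events["event_type"],
    ):
        dates = pd.date_range(start, end, freq="D")
        rows.append(
            pd.DataFrame(
                {"location_id": loc, "date": dates, "event_type": etype}
            )
        )
    out = pd.concat(rows, ignore_index=True)
    if out.duplicated(["location_id", "date"]).any():
        raise ValueError("overlapping heatwave events for a location (construction bug)")
    return out


def compute_daily_hwi(
    climate: pd.DataFrame,
    thresholds: ThresholdSet,
    events: pd.DataFrame,
    zero_off_type: bool = False,
) -> pd.DataFrame:
    """Daily daytime (dhwi) and nighttime (nhwi) heatwave indices.

    On every day inside an event, dhwi = max(0, tmax - tmax_threshold) and
    nhwi = max(0, tmin - tmin_threshold); all other season days get zeros
    ("HWIs are coded 0 on non-heatwave days"). Both indices are computed on
    every heatwave day regardless of the containing event's classification;
    pass ``zero_off_type=True`` to zero the off-type index instead. Binary
    flags ``dhw_flag``/``nhw_flag`` mark membership in daytime- and
    nighttime-accentuated events and are mutually exclusive.

    Days present in ``climate`` with missing tmax/tmin yield missing exposure
    (NaN indices) so they can be excluded downstream.
    """
    clim = _as_climate(climate)
    clim = clim[_season_mask(clim["date"], thresholds.season_months)]
    df = _join_thresholds(clim, thresholds).sort_values(
        ["location_id", "date"]
    ).reset_index(drop=True)

    ev_days = _explode_event_days(events)
    df = df.merge(ev_days, on=["location_id", "date"], how="left")
    in_event = df["event_type"].notna()

    excess_x = (df["tmax"] - df["tmax_threshold"]).clip(lower=0.0)
    excess_n = (df["tmin"] - df["tmin_threshold"]).clip(lower=0.0)
    df["dhwi"] = np.where(in_event, excess_x, 0.0)
    df["nhwi"] = np.where(in_event, excess_n, 0.0)
    invalid = df["tmax"].isna() | df["tmin"].isna()
    df.loc[invalid, ["dhwi", "nhwi"]] = np.nan
    df["dhw_flag"] = (in_event & df["event_type"].eq(DAYTIME)).astype(int)
    df["nhw_flag"] = (in_event & df["event_type"].eq(NIGHTTIME)).astype(int)
    if zero_off_type:
        df.loc[df["nhw_flag"] == 1, "dhwi"] = 0.0
        df.loc[df["dhw_flag"] == 1, "nhwi"] = 0.0
    cols = ["location_id", "date", "dhwi", "nhwi", "dhw_flag", "nhw_flag"]
    if "rh" in df.columns:
        cols.append("rh")
    return df[cols]


def compute_exposure(
    climate: pd.DataFrame,
    thresholds: ThresholdSet,
    min_duration: int = 2,
    zero_off_type: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: detect events and compute daily HWIs in one step."""
    events = detect_heatwave_events(climate, thresholds, min_duration=min_duration)
    exposure = compute_daily_hwi(
        climate, thresholds, events, zero_off_type=zero_off_type
    )
    return events, exposure
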