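"""Growing-season aggregation of daily station meteorology.

The winter-wheat growing window runs from sowing in early October —
day-of-year 273 of the year before harvest — through harvest in late May —
day-of-year 145 of the harvest year, inclusive on both ends (238 days for a
non-leap pair: 365 - 273 + 1 + 145).  Day-of-year is taken in each calendar year's own calendar,
so the window start/end calendar dates wobble by one day around leap years.

Per season and station:

    T = sum of daily mean temperature (tmax + tmin)/2 over the window  [degC]
    P = sum of daily precipitation                                     [mm]
    h = sum of daily sunshine hours                                    [h]

The accumulated temperature T is a caloric index of heat availability; no
base-temperature cutoff is applied.  The regional value is the unweighted
mean across stations.  Missing days (up to 5% per station) are filled by
linear interpolation for temperature, zero for precipitation, and the
station-month mean for sunshine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SeasonMet", "season_window", "aggregate_season", "aggregate_seasons"]

SOWING_DOY = 273
HARVEST_DOY = 145

MET_COLUMNS = ["date", "station", "tmax_c", "tmin_c", "precip_mm", "sunshine_h"]


@dataclass
class SeasonMet:
    """Accumulated meteorology for one growing season (labelled by harvest year)."""

    season: int
    T: float  # accumulated temperature, degC (sum of daily means)
    P: float  # precipitation, mm
    h: float  # sunshine, hours
    stations_used: int


def season_window(harvest_year: int) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Inclusive (start, end) dates of the growing window for a harvest year.

    Start is day 273 of harvest_year - 1, end is day 145 of harvest_year,
    each computed in that calendar year's own calendar.
    """
    start = pd.Timestamp(harvest_year - 1, 1, 1) + pd.Timedelta(days=SOWING_DOY - 1)
    end = pd.Timestamp(harvest_year, 1, 1) + pd.Timedelta(days=HARVEST_DOY - 1)
    return start, end


def _fill_station(frame: pd.DataFrame, index: pd.DatetimeIndex) -> pd.DataFrame:
    """Reindex one station's window to daily resolution and fill gaps."""
    f = frame.set_index("date").reindex(index)
    for col in ("tmax_c", "tmin_c"):
        f[col] = f[col].interpolate(method="linear", limit_direction="both")
    f["precip_mm"] = f["precip_mm"].fillna(0.0)
    if f["sunshine_h"].isna().any():
        month_means = f.groupby(f.index.month)["sunshine_h"].transform("mean")
        f["sunshine_h"] = f["sunshine_h"].fillna(month_means)
        f["sunshine_h"] = f["sunshine_h"].fillna(f["sunshine_h"].mean())
    return f


def aggregate_season(
    daily: pd.DataFrame, harvest_year: int, max_missing_frac: float = 0.05
) -> SeasonMet:
    """Aggregate a daily meteorology table over one growing window.

    `daily` needs columns date, station, tmax_c, tmin_c, precip_mm,
    sunshine_h.  A station missing more than `max_missing_frac` of the
    window's days is a coverage error.
    """
    missing = [c for c in MET_COLUMNS if c not in daily.columns]
    if missing:
        raise ValueError(f"daily table lacks columns {missing}")
    start, end = season_window(harvest_year)
    idx = pd.date_range(start, end, freq="D")
    dates = pd.to_datetime(daily["date"])
    window = daily.loc[(dates >= start) & (dates <= end)].copy()
    window["date"] = pd.to_datetime(window["date"])
    if window.empty:
        raise ValueError(f"no meteorology records inside window {start.date()}..{end.date()}")

    T_list, P_list, h_list = [], [], []
    for station, frame in window.groupby("station"):
        n_missing = len(idx) - frame["date"].nunique()
        if n_missing > max_missing_frac * len(idx):
            raise ValueError(
                f"station {station!r} misses {n_missing}/{len(idx)} days in "
                f"window {start.date()}..{end.date()}"
            )
        f = _fill_station(frame, idx)
        T_list.append(float(((f["tmax_c"] + f["tmin_c"]) / 2.0).sum()))
        P_list.append(float(f["precip_mm"].sum()))
        h_list.append(float(f["sunshine_h"].sum()))

    return SeasonMet(
        season=int(harvest_year),
        T=float(np.mean(T_list)),
        P=float(np.mean(P_list)),
        h=float(np.mean(h_list)),
        stations_used=len(T_list),
    )


def aggregate_seasons(daily: pd.DataFrame, years) -> pd.DataFrame:
    """Aggregate every requested harvest year; returns a tidy season table."""
    rows = [aggregate_season(daily, int(y)) for y in years]
    return pd.DataFrame(
        {
            "season": [r.season for r in rows],
            "T": [r.T for r in rows],
            "P": [r.P for r in rows],
            "h": [r.h for r in rows],
            "stations_used": [r.stations_used for r in rows],
        }
    )
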