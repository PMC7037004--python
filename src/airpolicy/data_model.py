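"""Ingest and feature construction for daily air-quality series.

Builds the analysis date index, city-averaged weather, wind-quadrant speeds,
calendar dummies (weekends, Italian public holidays and their interactions)
and log-scale pollutant series from long-format station data, and assembles
the per-day regressor matrix used by the structural model, including the
policy step and impulse dummies.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from dateutil import easter

logger = logging.getLogger("airpolicy")

#: canonical regressor column order (policy columns last)
REGRESSOR_ORDER = (
    "counterfactual",
    "holidays",
    "weekend",
    "saturday_holidays",
    "sunday_holidays",
    "q_ne",
    "q_se",
    "q_sw",
    "q_nw",
    "temperature",
    "rainfall",
    "radiation",
    "humidity",
    "policy_step",
    "policy_impulse",
)

WEATHER_VARIABLES = (
    "temperature",
    "rainfall",
    "humidity",
    "radiation",
    "wind_speed",
    "wind_direction",
)


# ---------------------------------------------------------------------------
# date index
# ---------------------------------------------------------------------------

def build_date_index(start_date, end_date) -> pd.DatetimeIndex:
    """Inclusive contiguous daily date range (leap days included).

    Raises ``ValueError`` on invalid or reversed dates.
    """
    start = pd.Timestamp(start_date)
    end = pd.Timestamp(end_date)
    if start > end:
        raise ValueError(f"reversed date range: {start.date()} > {end.date()}")
    return pd.date_range(start, end, freq="D")


# ---------------------------------------------------------------------------
# daily series container
# ---------------------------------------------------------------------------

@dataclass
class DailySeries:
    """One variable observed on a contiguous daily index, missing allowed.

    ``values`` is a float Series indexed by normalized daily Timestamps;
    ``log_scale`` records whether a natural-log transform has been applied.
    """

    station_id: str
    variable: str
    values: pd.Series
    log_scale: bool = False

    def __post_init__(self) -> None:
        idx = pd.DatetimeIndex(self.values.index)
        if len(idx) == 0:
            raise ValueError("empty series")
        if idx.has_duplicates:
            raise ValueError("duplicate dates in series")
        if not idx.is_monotonic_increasing:
            raise ValueError("dates not strictly increasing")
        if len(idx) > 1:
            steps = np.unique(np.diff(idx.values).astype("timedelta64[D]"))
            if steps.size != 1 or steps[0] != np.timedelta64(1, "D"):
                raise ValueError("date index is not contiguous daily")
        self.values = self.values.astype(float)
        self.values.index = idx

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.values.index)

    def reindex(self, index: pd.DatetimeIndex) -> "DailySeries":
        return replace(self, values=self.values.reindex(index))


def log_transform(series: DailySeries) -> DailySeries:
    """Natural log of a positive concentration series.

    Non-positive or missing inputs become missing; the count of degenerate
    values is logged. Idempotence is refused: the input must be raw scale.
    """
    if series.log_scale:
        raise ValueError("series is already on the log scale")
    vals = series.values.to_numpy(copy=True)
    bad = np.isfinite(vals) & (vals <= 0.0)
    n_bad = int(bad.sum())
    if n_bad:
        logger.info(
            "log_transform(%s/%s): %d non-positive values set to missing",
            series.station_id, series.variable, n_bad,
        )
    vals[bad] = np.nan
    with np.errstate(invalid="ignore"):
        out = np.log(vals)
    return DailySeries(
        station_id=series.station_id,
        variable=series.variable,
        values=pd.Series(out, index=series.values.index),
        log_scale=True,
    )


# ---------------------------------------------------------------------------
# weather aggregation
# ---------------------------------------------------------------------------

def city_average_weather(series_by_station: dict[str, DailySeries], variable: str) -> DailySeries:
    """Per-day arithmetic mean over stations reporting the variable.

    A day is missing iff all stations are missing that day.
    """
    matching = {
        sid: s for sid, s in series_by_station.items() if s.variable == variable
    }
    if not matching:
        known = sorted({s.variable for s in series_by_station.values()})
        raise ValueError(f"unknown variable {variable!r}; available: {known}")
    frame = pd.DataFrame({sid: s.values for sid, s in matching.items()})
    mean = frame.mean(axis=1, skipna=True)
    return DailySeries(station_id="city_average", variable=variable, values=mean)


@dataclass(frozen=True)
class WindQuadrantDay:
    """Mean wind speed (m/s) per compass quadrant for one day.

    A quadrant is 0 when no station reports a direction falling in it.
    """

    q_ne: float
    q_se: float
    q_sw: float
    q_nw: float

    def __post_init__(self) -> None:
        for name in ("q_ne", "q_se", "q_sw", "q_nw"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


def wind_to_quadrants(direction_by_station, speed_by_station) -> WindQuadrantDay:
    """Assign each station's (direction, speed) pair to one compass quadrant.

    Quadrants are half-open in clockwise degrees — NE: [0, 90), SE: [90, 180),
    SW: [180, 270), NW: [270, 360) — with 360 mapped to 0, so every direction
    belongs to exactly one quadrant. The quadrant value is the mean speed of
    the assigned stations (0 when none). Stations with a missing direction or
    speed are skipped; directions outside [0, 360] are rejected.
    """
    dirs = pd.Series(direction_by_station, dtype=float)
    spds = pd.Series(speed_by_station, dtype=float)
    sums = np.zeros(4)
    counts = np.zeros(4, dtype=int)
    for sid, d in dirs.items():
        v = spds.get(sid, np.nan)
        if not (np.isfinite(d) and np.isfinite(v)):
            continue
        if d < 0.0 or d > 360.0:
            raise ValueError(f"wind direction {d} for station {sid!r} outside [0, 360]")
        if v < 0.0:
            raise ValueError(f"negative wind speed {v} for station {sid!r}")
        q = int((d % 360.0) // 90.0)
        sums[q] += v
        counts[q] += 1
    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return WindQuadrantDay(*means)


def daily_wind_quadrants(
    direction_by_station: dict[str, DailySeries],
    speed_by_station: dict[str, DailySeries],
) -> pd.DataFrame:
    """Quadrant speed columns (q_ne, q_se, q_sw, q_nw) over a shared index."""
    dir_frame = pd.DataFrame({k: s.values for k, s in direction_by_station.items()})
    spd_frame = pd.DataFrame({k: s.values for k, s in speed_by_station.items()})
    idx = dir_frame.index.union(spd_frame.index)
    rows = []
    for day in idx:
        d = dir_frame.reindex([day]).iloc[0] if day in dir_frame.index else pd.Series(dtype=float)
        v = spd_frame.reindex([day]).iloc[0] if day in spd_frame.index else pd.Series(dtype=float)
        q = wind_to_quadrants(d.to_dict(), v.to_dict())
        rows.append((q.q_ne, q.q_se, q.q_sw, q.q_nw))
    return pd.DataFrame(rows, index=idx, columns=["q_ne", "q_se", "q_sw", "q_nw"])


# ---------------------------------------------------------------------------
# calendar features
# ---------------------------------------------------------------------------

def italian_holidays(years) -> list[dt.date]:
    """Italian national public holidays: fixed dates plus Easter Sunday/Monday."""
    fixed = [(1, 1), (1, 6), (4, 25), (5, 1), (6, 2), (8, 15), (11, 1), (12, 8), (12, 25), (12, 26)]
    out: list[dt.date] = []
    for y in years:
        out.extend(dt.date(y, m, d) for m, d in fixed)
        e = easter.easter(y)
        out.append(e)
        out.append(e + dt.timedelta(days=1))
    return sorted(out)


def build_calendar(dates: pd.DatetimeIndex, holiday_list=None) -> pd.DataFrame:
    """Holiday/weekend indicator columns for the given dates.

    ``holiday_list`` is an explicit iterable of dates, or None for the Italian
    national calendar of the years spanned by ``dates``. Columns: holidays,
    weekend, saturday_holidays, sunday_holidays.
    """
    dates = pd.DatetimeIndex(dates)
    if holiday_list is None:
        holiday_list = italian_holidays(range(dates[0].year, dates[-1].year + 1))
    hol = pd.DatetimeIndex(pd.to_datetime(list(holiday_list)))
    is_hol = dates.isin(hol).astype(float)
    dow = dates.dayofweek  # Monday=0
    weekend = ((dow == 5) | (dow == 6)).astype(float)
    sat_hol = is_hol * (dow == 5)
    sun_hol = is_hol * (dow == 6)
    return pd.DataFrame(
        {
            "holidays": is_hol,
            "weekend": weekend,
            "saturday_holidays": sat_hol,
            "sunday_holidays": sun_hol,
        },
        index=dates,
    )


# ---------------------------------------------------------------------------
# regressor assembly
# ---------------------------------------------------------------------------

@dataclass
class RegressorSet:
    """Per-day design matrix for the measurement equation.

    Holds calendar dummies, wind-quadrant speeds, optional weather columns,
    the log counterfactual series, and the policy step/impulse dummies
    (``policy_step`` is 0 before the policy date and 1 from it onward;
    ``policy_impulse`` is 1 on the policy date only).
    """

    frame: pd.DataFrame
    policy_date: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        idx = pd.DatetimeIndex(self.frame.index)
        if len(idx) > 1:
            steps = np.unique(np.diff(idx.values).astype("timedelta64[D]"))
            if steps.size != 1 or steps[0] != np.timedelta64(1, "D"):
                raise ValueError("regressor index is not contiguous daily")
        order = [c for c in REGRESSOR_ORDER if c in self.frame.columns]
        extra = [c for c in self.frame.columns if c not in REGRESSOR_ORDER]
        self.frame = self.frame[order + extra].astype(float)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.frame.index)

    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def matrix(self, names, index=None) -> np.ndarray:
        """Design matrix for the named columns (order preserved)."""
        missing = [n for n in names if n not in self.frame.columns]
        if missing:
            raise KeyError(f"unknown regressor columns: {missing}")
        sub = self.frame if index is None else self.frame.reindex(index)
        return sub[list(names)].to_numpy()

    def subset(self, index: pd.DatetimeIndex) -> "RegressorSet":
        return RegressorSet(self.frame.reindex(index), policy_date=self.policy_date)


def policy_dummies(dates: pd.DatetimeIndex, policy_date) -> pd.DataFrame:
    """Step dummy (1 from the policy date onward) and impulse dummy (policy date only)."""
    dates = pd.DatetimeIndex(dates)
    p = pd.Timestamp(policy_date)
    step = (dates >= p).astype(float)
    impulse = (dates == p).astype(float)
    return pd.DataFrame({"policy_step": step, "policy_impulse": impulse}, index=dates)


def assemble_regressors(
    calendar: pd.DataFrame,
    quadrants: pd.DataFrame | None = None,
    counterfactual_log: DailySeries | None = None,
    policy_date=None,
    weather: pd.DataFrame | None = None,
) -> RegressorSet:
    """Join the feature blocks into one RegressorSet on the calendar's index.

    All inputs must share the calendar's date index; misalignment is rejected
    with the offending ranges named.
    """
    idx = pd.DatetimeIndex(calendar.index)
    parts = [calendar]

    def _check(name: str, other_idx) -> None:
        other_idx = pd.DatetimeIndex(other_idx)
        if not other_idx.equals(idx):
            raise ValueError(
                f"{name} index misaligned: spans {other_idx[0].date()}..{other_idx[-1].date()} "
                f"vs calendar {idx[0].date()}..{idx[-1].date()}"
            )

    if quadrants is not None:
        _check("wind quadrants", quadrants.index)
        parts.append(quadrants)
    if weather is not None:
        _check("weather", weather.index)
        parts.append(weather)
    if counterfactual_log is not None:
        if not counterfactual_log.log_scale:
            raise ValueError("counterfactual series must be log-transformed")
        _check("counterfactual", counterfactual_log.dates)
        parts.append(counterfactual_log.values.rename("counterfactual").to_frame())
    frame = pd.concat(parts, axis=1)
    ts = None
    if policy_date is not None:
        ts = pd.Timestamp(policy_date)
        frame = pd.concat([frame, policy_dummies(idx, ts)], axis=1)
    return RegressorSet(frame, policy_date=ts)


# ---------------------------------------------------------------------------
# long-format ingest
# ---------------------------------------------------------------------------

def read_long_csv(path) -> dict[tuple[str, str], DailySeries]:
    """Read a long CSV ``date,station_id,variable,value`` into DailySeries.

    Each (station, variable) pair is reindexed onto its own full daily span;
    per-pair missing counts are logged.
    """
    df = pd.read_csv(path, dtype={"station_id": str, "variable": str})
    required = {"date", "station_id", "variable", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    out: dict[tuple[str, str], DailySeries] = {}
    for (sid, var), grp in df.groupby(["station_id", "variable"], sort=True):
        grp = grp.sort_values("date")
        if grp["date"].duplicated().any():
            raise ValueError(f"{path}: duplicate dates for {sid}/{var}")
        idx = build_date_index(grp["date"].iloc[0], grp["date"].iloc[-1])
        vals = grp.set_index("date")["value"].reindex(idx)
        n_missing = int(vals.isna().sum())
        if n_missing:
            logger.info("ingest %s/%s: %d missing days of %d", sid, var, n_missing, len(idx))
        out[(sid, var)] = DailySeries(station_id=sid, variable=var, values=vals)
    return out


def read_station_metadata(path) -> pd.DataFrame:
    """Station metadata CSV: station_id, name, kind, role."""
    df = pd.read_csv(path, dtype=str)
    required = {"station_id", "name", "kind", "role"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    bad_kind = set(df["kind"]) - {"air_quality", "weather"}
    if bad_kind:
        raise ValueError(f"{path}: unknown station kind {sorted(bad_kind)}")
    return df.set_index("station_id")
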