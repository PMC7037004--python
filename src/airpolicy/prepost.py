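"""Pre/post treatment-control comparison of concentration levels.

Compares a treatment-year calendar window (the months following the policy
start) against the multi-year average of the same calendar days in control
years, through two difference statistics: dAVG (difference of means) and
dMED (difference of medians, robust to the heavy right tail of concentration
data). Both operate on raw-scale series in ug/m3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import DailySeries


@dataclass(frozen=True)
class Window:
    """A calendar window given as month-day endpoints, e.g. 02-25 .. 09-30."""

    start_month: int
    start_day: int
    end_month: int
    end_day: int

    @classmethod
    def parse(cls, text: str) -> "Window":
        """Parse ``MM-DD:MM-DD``."""
        try:
            a, b = text.split(":")
            sm, sd = (int(x) for x in a.split("-"))
            em, ed = (int(x) for x in b.split("-"))
        except ValueError as exc:
            raise ValueError(f"cannot parse window {text!r}, expected MM-DD:MM-DD") from exc
        return cls(sm, sd, em, ed)

    def day_labels(self) -> list[tuple[int, int]]:
        """(month, day) labels covered by the window, Feb 29 excluded.

        Feb 29 has no counterpart in non-leap control years, so it is dropped
        from calendar-day matching altogether.
        """
        # use a non-leap reference year to enumerate labels
        ref = pd.date_range(
            f"2019-{self.start_month:02d}-{self.start_day:02d}",
            f"2019-{self.end_month:02d}-{self.end_day:02d}",
            freq="D",
        )
        if len(ref) == 0:
            raise ValueError("empty window")
        return [(d.month, d.day) for d in ref]


#: the study's window: policy start (25 Feb) through 30 Sep
DEFAULT_WINDOW = Window(2, 25, 9, 30)


@dataclass(frozen=True)
class PrePostResult:
    """dAVG/dMED differences (ug/m3) with the realized window sizes."""

    d_avg: float
    d_med: float
    n_treat: int
    n_control_days: int
    window_days: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.d_avg) and np.isfinite(self.d_med)


def _window_values(series: DailySeries, year: int, window: Window) -> pd.Series:
    """Values of one year's window, indexed by (month, day) labels."""
    labels = window.day_labels()
    dates = [pd.Timestamp(year=year, month=m, day=d) for m, d in labels]
    vals = series.values.reindex(pd.DatetimeIndex(dates))
    return pd.Series(vals.to_numpy(), index=pd.MultiIndex.from_tuples(labels))


def control_daily_average(series: DailySeries, control_years, window: Window = DEFAULT_WINDOW) -> pd.Series:
    """Per-calendar-day control mean c_j over the available control years.

    For each calendar day j in the window, c_j is the mean of that day's
    observations over the control years; years missing day j are excluded
    from both numerator and denominator. c_j is missing iff every control
    year is missing on day j.
    """
    control_years = list(control_years)
    if not control_years:
        raise ValueError("control_years must be non-empty")
    cols = {y: _window_values(series, y, window) for y in control_years}
    frame = pd.DataFrame(cols)
    return frame.mean(axis=1, skipna=True)


def diff_of_central_values(u, v) -> PrePostResult:
    """dAVG = mean(U) - mean(V) and dMED = median(U) - median(V).

    Means and medians are taken over non-missing values only; an even count
    median is the midpoint of the two central order statistics. A window with
    zero non-missing values yields an undefined (NaN) result.
    """
    u = np.asarray(pd.Series(u), dtype=float)
    v = np.asarray(pd.Series(v), dtype=float)
    un = u[np.isfinite(u)]
    vn = v[np.isfinite(v)]
    if un.size == 0 or vn.size == 0:
        return PrePostResult(np.nan, np.nan, un.size, vn.size, max(u.size, v.size))
    return PrePostResult(
        d_avg=float(un.mean() - vn.mean()),
        d_med=float(np.median(un) - np.median(vn)),
        n_treat=int(un.size),
        n_control_days=int(vn.size),
        window_days=int(max(u.size, v.size)),
    )


def prepost_compare(
    series: DailySeries,
    treat_year: int,
    control_years,
    window: Window = DEFAULT_WINDOW,
) -> PrePostResult:
    """Full pre/post comparison for one station series on the raw scale."""
    if series.log_scale:
        raise ValueError("pre/post statistics are defined on raw concentrations")
    u = _window_values(series, treat_year, window)
    v = control_daily_average(series, control_years, window)
    return diff_of_central_values(u, v)


def prepost_table(
    series_list: list[DailySeries],
    treat_year: int,
    control_years,
    window: Window = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """dAVG/dMED rows for several stations, mirroring the study's summary table."""
    rows = []
    for s in series_list:
        r = prepost_compare(s, treat_year, control_years, window)
        rows.append(
            {
                "station_id": s.station_id,
                "pollutant": s.variable,
                "dAVG": r.d_avg,
                "dMED": r.d_med,
                "n_treat": r.n_treat,
                "n_control_days": r.n_control_days,
                "window_days": r.window_days,
            }
        )
    return pd.DataFrame(rows)
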