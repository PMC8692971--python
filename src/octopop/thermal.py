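"""Marine-heatwave statistics from daily temperature series.

A day-of-year climatology (mean and 90th-percentile threshold) is built
over a fixed baseline period by pooling observations in a window around
each calendar day and smoothing with a centred moving average.  Marine
heatwave (MHW) events are maximal runs of days strictly warmer than the
day-of-year threshold lasting at least five days; events separated by a
short below-threshold gap are merged, with the gap days not counting as
MHW days.  MHW days are summarised per year over the warm hydrological
season (June-November, "JJASON").

For in-situ logger records a simpler indicator is used: extreme heat
days are days above the inter-annual 90th percentile of the whole daily
record that also reach an absolute sublethal floor (23 degC by default),
with years flagged when any daily mean reaches the lethal floor (25
degC).
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DailyTemperatureSeries",
    "Climatology",
    "MHWEvent",
    "ExtremeHeatSummary",
    "daily_means",
    "build_climatology",
    "detect_mhw_events",
    "mhw_days_per_year",
    "extreme_heat_days",
    "read_temperature_csv",
    "JJASON",
]

JJASON = (6, 7, 8, 9, 10, 11)

# day-of-year on the 366-day leap calendar (Feb 29 = 60, Dec 31 = 366)
_LEAP_DOY = {
    (d.month, d.day): i + 1
    for i, d in enumerate(
        dt.date(2000, 1, 1) + dt.timedelta(days=k) for k in range(366)
    )
}
_FEB29 = _LEAP_DOY[(2, 29)]  # 60


def _leap_doy(dates: pd.DatetimeIndex) -> np.ndarray:
    return np.array([_LEAP_DOY[(d.month, d.day)] for d in dates], dtype=np.int64)


@dataclass(frozen=True)
class DailyTemperatureSeries:
    """Contiguous daily temperatures; NaN marks a missing day."""

    dates: pd.DatetimeIndex
    temps_c: np.ndarray

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        temps = np.asarray(self.temps_c, dtype=float)
        if len(dates) != len(temps):
            raise ValueError("dates and temps_c must have equal length")
        if len(dates) == 0:
            raise ValueError("empty temperature series")
        deltas = np.diff(dates.values.astype("datetime64[D]").astype(np.int64))
        if not (deltas == 1).all():
            raise ValueError("dates must be contiguous calendar days")
        if np.isinf(temps).any():
            raise ValueError("temperatures must be finite where present")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "temps_c", temps)

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def years(self) -> np.ndarray:
        return self.dates.year.to_numpy()

    def subset_years(self, first: int, last: int) -> "DailyTemperatureSeries":
        mask = (self.years >= first) & (self.years <= last)
        if not mask.any():
            raise ValueError(f"series has no data in {first}-{last}")
        return DailyTemperatureSeries(self.dates[mask], self.temps_c[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "temp_c": self.temps_c})


def read_temperature_csv(path, timestamp_col: str = "timestamp",
                         temp_col: str = "temp_c") -> DailyTemperatureSeries:
    """Read a daily or hourly CSV; hourly input is reduced to daily means."""
    df = pd.read_csv(path)
    for col in (timestamp_col, temp_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    ts = pd.to_datetime(df[timestamp_col])
    if (ts.dt.normalize() == ts).all() and not ts.duplicated().any():
        dates = pd.DatetimeIndex(ts)
        temps = df[temp_col].to_numpy(dtype=float)
        full = pd.date_range(dates.min(), dates.max(), freq="D")
        out = pd.Series(temps, index=dates).reindex(full)
        return DailyTemperatureSeries(full, out.to_numpy())
    return daily_means(ts, df[temp_col].to_numpy(dtype=float))


def daily_means(
    timestamps: Iterable, temps_c: Sequence[float], min_readings: int = 20
) -> DailyTemperatureSeries:
    """Reduce sub-daily readings to calendar-day means.

    Days with fewer than ``min_readings`` readings (default 20 of 24
    hourly values) are flagged missing rather than averaged.
    """
    ts = pd.to_datetime(pd.Series(list(timestamps)))
    if ts.empty:
        raise ValueError("empty input")
    frame = pd.DataFrame({"day": ts.dt.normalize(), "temp": np.asarray(temps_c, float)})
    grouped = frame.groupby("day")["temp"].agg(["mean", "count"])
    grouped.loc[grouped["count"] < min_readings, "mean"] = np.nan
    full = pd.date_range(grouped.index.min(), grouped.index.max(), freq="D")
    means = grouped["mean"].reindex(full)
    return DailyTemperatureSeries(full, means.to_numpy())


@dataclass(frozen=True)
class Climatology:
    """Per day-of-year baseline mean and 90th-percentile threshold.

    Arrays are indexed by leap-calendar day-of-year minus one
    (so entry 59 is Feb 29, interpolated from its neighbours).
    """

    mean_c: np.ndarray
    threshold_c: np.ndarray
    baseline_years: tuple[int, int]
    percentile: float = 90.0

    def __post_init__(self) -> None:
        for name, arr in (("mean_c", self.mean_c), ("threshold_c", self.threshold_c)):
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (366,):
                raise ValueError(f"{name} must have 366 entries, got {arr.shape}")
            object.__setattr__(self, name, arr)
        if (self.threshold_c < self.mean_c - 1e-9).any():
            warnings.warn(
                "climatology threshold below climatological mean on some days",
                stacklevel=2,
            )

    def threshold_for(self, dates: pd.DatetimeIndex) -> np.ndarray:
        return self.threshold_c[_leap_doy(dates) - 1]

    def mean_for(self, dates: pd.DatetimeIndex) -> np.ndarray:
        return self.mean_c[_leap_doy(dates) - 1]


def _circular_smooth(values: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return values
    half = width // 2
    padded = np.concatenate([values[-half:], values, values[:half]])
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    return np.convolve(padded, kernel, mode="valid")


def build_climatology(
    series: DailyTemperatureSeries,
    baseline_years: tuple[int, int] = (1982, 2011),
    window_halfwidth_days: int = 5,
    smoothing_days: int = 31,
    percentile: float = 90.0,
    min_coverage: float = 0.8,
) -> Climatology:
    """Fixed-baseline day-of-year climatology (mean + percentile threshold).

    For each day of year, observations from the baseline years within
    ``+/- window_halfwidth_days`` (circularly across year ends) are
    pooled; the mean and the ``percentile`` (linear-interpolation
    convention) of the pool give the climatological mean and threshold.
    Both are then smoothed with a centred ``smoothing_days``-wide moving
    average.  Feb 29 is the average of Feb 28 and Mar 1.
    """
    y0, y1 = baseline_years
    base = series.subset_years(y0, y1)
    n_expected = (dt.date(y1, 12, 31) - dt.date(y0, 1, 1)).days + 1
    n_present = int(np.isfinite(base.temps_c).sum())
    if n_present < min_coverage * n_expected:
        raise ValueError(
            f"baseline {y0}-{y1} coverage {n_present}/{n_expected} days "
            f"({n_present / n_expected:.0%}) is below the "
            f"{min_coverage:.0%} requirement"
        )

    ok = np.isfinite(base.temps_c)
    doy = _leap_doy(base.dates[ok])
    temps = base.temps_c[ok]
    # collapse to the 365-day circle: drop Feb 29 obs, shift later days down
    keep = doy != _FEB29
    pos = np.where(doy > _FEB29, doy - 2, doy - 1)[keep]  # 0..364
    temps = temps[keep]

    w = window_halfwidth_days
    mean365 = np.empty(365)
    thr365 = np.empty(365)
    for d in range(365):
        dist = np.abs(pos - d)
        pool = temps[np.minimum(dist, 365 - dist) <= w]
        if pool.size == 0:
            raise ValueError(
                f"no baseline observations for day-of-year {d + 1} "
                f"(+/-{w} d window): coverage gap"
            )
        mean365[d] = pool.mean()
        thr365[d] = np.percentile(pool, percentile)

    mean365 = _circular_smooth(mean365, smoothing_days)
    thr365 = _circular_smooth(thr365, smoothing_days)

    def expand(a365: np.ndarray) -> np.ndarray:
        out = np.empty(366)
        out[: _FEB29 - 1] = a365[: _FEB29 - 1]
        out[_FEB29:] = a365[_FEB29 - 1 :]
        out[_FEB29 - 1] = 0.5 * (a365[_FEB29 - 2] + a365[_FEB29 - 1])
        return out

    return Climatology(
        mean_c=expand(mean365),
        threshold_c=expand(thr365),
        baseline_years=(y0, y1),
        percentile=percentile,
    )


@dataclass(frozen=True)
class MHWEvent:
    """A detected marine-heatwave event.

    ``duration_days`` spans start..end inclusive (it includes any merged
    below-threshold gap); ``mhw_days`` lists only the exceedance days,
    which are what per-year day counts are built from.
    """

    start: pd.Timestamp
    end: pd.Timestamp
    mhw_days: tuple[pd.Timestamp, ...]
    max_exceedance_c: float
    mean_exceedance_c: float

    @property
    def duration_days(self) -> int:
        return (self.end - self.start).days + 1

    @property
    def n_mhw_days(self) -> int:
        return len(self.mhw_days)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] index runs of True."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def detect_mhw_events(
    series: DailyTemperatureSeries,
    climatology: Climatology,
    min_duration: int = 5,
    max_gap: int = 2,
) -> list[MHWEvent]:
    """Detect MHW events: runs of > threshold days of length >= min_duration.

    Missing days break runs.  Two qualifying events separated by at most
    ``max_gap`` observed below-threshold days are merged into one event;
    the gap days do not count as MHW days.
    """
    if min_duration < 1:
        raise ValueError("min_duration must be >= 1")
    thr = climatology.threshold_for(series.dates)
    present = np.isfinite(series.temps_c)
    # strict exceedance, with a 1e-9 degC guard against float noise in the
    # smoothed threshold (a constant series must never exceed itself)
    exceed = present & (series.temps_c - thr > 1e-9)

    core = [r for r in _runs(exceed) if r[1] - r[0] + 1 >= min_duration]

    merged: list[list[tuple[int, int]]] = []
    for run in core:
        if merged:
            prev_end = merged[-1][-1][1]
            gap = slice(prev_end + 1, run[0])
            gap_len = run[0] - prev_end - 1
            if gap_len <= max_gap and present[gap].all():
                merged[-1].append(run)
                continue
        merged.append([run])

    events: list[MHWEvent] = []
    for runs in merged:
        day_idx = np.concatenate([np.arange(a, b + 1) for a, b in runs])
        exc = series.temps_c[day_idx] - thr[day_idx]
        events.append(
            MHWEvent(
                start=series.dates[runs[0][0]],
                end=series.dates[runs[-1][1]],
                mhw_days=tuple(series.dates[day_idx]),
                max_exceedance_c=float(exc.max()),
                mean_exceedance_c=float(exc.mean()),
            )
        )
    return events


def mhw_days_per_year(
    events: Sequence[MHWEvent],
    months: Sequence[int] = JJASON,
    years: Sequence[int] | None = None,
) -> dict[int, int]:
    """Count MHW days per year restricted to the given calendar months.

    An event spanning a month (or year) boundary contributes only the
    days inside the window.  ``years`` pre-seeds the output with zeros so
    event-free years are reported explicitly.
    """
    months = set(months)
    counts: dict[int, int] = {int(y): 0 for y in years} if years else {}
    for ev in events:
        for day in ev.mhw_days:
            if day.month in months:
                counts[day.year] = counts.get(day.year, 0) + 1
    return dict(sorted(counts.items()))


@dataclass(frozen=True)
class ExtremeHeatSummary:
    """Per-year extreme-heat-day counts from an in-situ daily record."""

    threshold_c: float  # inter-annual 90th percentile of the record
    min_temp_c: float
    lethal_temp_c: float
    days_per_year: dict[int, int] = field(default_factory=dict)
    lethal_years: tuple[int, ...] = ()


def extreme_heat_days(
    series: DailyTemperatureSeries,
    min_temp_c: float = 23.0,
    lethal_temp_c: float = 25.0,
    percentile: float = 90.0,
    months: Sequence[int] | None = None,
) -> ExtremeHeatSummary:
    """Count days above the record-wide percentile that reach the floor.

    The percentile is inter-annual: computed over every available daily
    mean in the record (all calendar days pooled), not day-of-year
    resolved.  A day counts when its temperature strictly exceeds that
    percentile AND reaches at least ``min_temp_c``.  Years with any daily
    mean at or above ``lethal_temp_c`` are flagged.  ``months`` optionally
    restricts both the percentile pool and the counting to a season.
    """
    temps = series.temps_c
    dates = series.dates
    if months is not None:
        keep = np.isin(dates.month, list(months))
        temps, dates = temps[keep], dates[keep]
    ok = np.isfinite(temps)
    if not ok.any():
        raise ValueError("no observed temperatures in series")
    threshold = float(np.percentile(temps[ok], percentile))

    hot = ok & (temps > threshold) & (temps >= min_temp_c)
    lethal = ok & (temps >= lethal_temp_c)
    years = dates.year.to_numpy()
    per_year = {int(y): int(hot[years == y].sum()) for y in np.unique(years)}
    lethal_years = tuple(int(y) for y in np.unique(years[lethal]))
    return ExtremeHeatSummary(
        threshold_c=threshold,
        min_temp_c=min_temp_c,
        lethal_temp_c=lethal_temp_c,
        days_per_year=per_year,
        lethal_years=lethal_years,
    )
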