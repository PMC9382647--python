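"""Robust-design calendar and ingestion of daily removal records.

Time is organised as an open robust design: each calendar year is divided
into fixed-length primary periods (default two weeks, giving 26 per year
cycle), and each primary period contains secondary occasions -- the active
trapping days.  The population is treated as closed within a primary period
except for removals and temporary emigration, and open between periods.

Day-of-year arithmetic uses a 365-day convention: in leap years Feb 29 is
merged into the February window, which lies outside the March--October
analysis window and is excluded anyway.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SEASONS",
    "StudyDesign",
    "RemovalSeries",
    "build_design",
    "ingest_records",
    "export_records",
]

#: The four biological seasons of the active year, in calendar order.
SEASONS = ("breeding", "hatching", "post-hatching", "pre-hibernation")

# Month -> season index.  The active season (Mar-Oct) follows the four
# biological seasons; winter months are folded into the adjacent labels
# (Nov-Dec with pre-hibernation, Jan-Feb with breeding) so that every
# period of the year cycle maps to exactly one season.
_MONTH_SEASON = {
    1: 0, 2: 0, 3: 0, 4: 0,
    5: 1, 6: 1,
    7: 2, 8: 2,
    9: 3, 10: 3, 11: 3, 12: 3,
}

_CUM_DAYS = np.cumsum([0, 31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


def _day_of_year_365(date: _dt.date) -> int:
    """Day of year on the 365-day convention (Feb 29 -> Feb 28)."""
    doy = date.timetuple().tm_yday
    if doy >= 60 and _is_leap(date.year):
        doy -= 1
    return doy


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def _month_of_doy(doy: int) -> int:
    """Month (1-12) containing a 365-convention day of year."""
    return int(np.searchsorted(_CUM_DAYS, doy, side="left"))


@dataclasses.dataclass
class StudyDesign:
    """The robust-design calendar for one management area.

    Attributes
    ----------
    years
        Consecutive calendar years covered by the study.
    period_length
        Length of a primary period in days (14 by default).
    max_period
        Number of primary periods in a full year cycle
        (``floor(365 / period_length)``; the final period absorbs the
        remainder days).
    seasons
        Season index (into :data:`SEASONS`) of each period, assigned by
        the calendar month of the period midpoint.
    birth_pulse_period
        1-based index of the period containing the birth-pulse
        anniversary (May 1 by default, period 9 under 14-day periods).
    sampled_mask
        ``(n_years, max_period)`` boolean; True where the period has at
        least one active trapping day.
    n_days
        ``(n_years, max_period)`` count of active trapping days.
    """

    years: tuple[int, ...]
    period_length: int
    max_period: int
    seasons: np.ndarray
    birth_pulse_period: int
    sampled_mask: np.ndarray
    n_days: np.ndarray

    @property
    def n_years(self) -> int:
        return len(self.years)

    def period_of_doy(self, doy: int) -> int:
        """1-based primary period containing a (365-convention) day of year."""
        return min((doy - 1) // self.period_length + 1, self.max_period)

    def day_within_period(self, doy: int) -> int:
        """1-based calendar day position within its period."""
        t = self.period_of_doy(doy)
        return doy - (t - 1) * self.period_length

    def season_labels(self) -> list[str]:
        return [SEASONS[s] for s in self.seasons]

    def summary(self) -> dict:
        """JSON-serializable description of the design."""
        return {
            "years": list(self.years),
            "period_length": self.period_length,
            "max_period": self.max_period,
            "birth_pulse_period": self.birth_pulse_period,
            "seasons": self.season_labels(),
            "n_days": self.n_days.tolist(),
            "sampled_periods_per_year": self.sampled_mask.sum(axis=1).tolist(),
        }


def build_design(
    years: Sequence[int],
    period_length: int = 14,
    birth_anniversary: tuple[int, int] = (5, 1),
) -> StudyDesign:
    """Build the robust-design calendar.

    Period 1 begins January 1; with the default two-week periods the
    year cycle has 26 periods and May 1 (day 121) falls in period 9.

    Parameters
    ----------
    years
        Non-empty, consecutive calendar years.
    period_length
        Days per primary period (>= 1).
    birth_anniversary
        ``(month, day)`` of the annual birth pulse.
    """
    years = tuple(int(y) for y in years)
    if not years:
        raise ValueError("years must be non-empty")
    if list(years) != list(range(years[0], years[0] + len(years))):
        raise ValueError(f"years must be consecutive, got {years}")
    if period_length < 1:
        raise ValueError("period_length must be >= 1")

    max_period = 365 // period_length
    # season of each period from the month of its midpoint day
    seasons = np.empty(max_period, dtype=np.int64)
    for t in range(1, max_period + 1):
        first = (t - 1) * period_length + 1
        last = t * period_length if t < max_period else 365
        mid = (first + last) // 2
        seasons[t - 1] = _MONTH_SEASON[_month_of_doy(mid)]

    bp_month, bp_day = birth_anniversary
    bp_doy = int(_CUM_DAYS[bp_month - 1]) + bp_day
    bp_period = min((bp_doy - 1) // period_length + 1, max_period)

    n_years = len(years)
    return StudyDesign(
        years=years,
        period_length=period_length,
        max_period=max_period,
        seasons=seasons,
        birth_pulse_period=bp_period,
        sampled_mask=np.zeros((n_years, max_period), dtype=bool),
        n_days=np.zeros((n_years, max_period), dtype=np.int64),
    )


@dataclasses.dataclass
class RemovalSeries:
    """Observed daily removals and trap effort under the robust design.

    Attributes
    ----------
    design
        The :class:`StudyDesign` (with ``n_days``/``sampled_mask`` filled
        in from the data).
    removals
        ``(n_years, max_period, max_days)`` daily removal counts; day
        slots are the active trapping days of the period in date order.
    effort
        ``(n_years, max_period)`` mean daily trap count over the active
        days of each period (the per-period effort entering the daily
        capture probability).
    period_totals
        ``(n_years, max_period)`` total removals per period.
    records
        The retained daily records (date, year_idx, period, day_idx,
        removals, traps), enabling lossless export.
    """

    design: StudyDesign
    removals: np.ndarray
    effort: np.ndarray
    period_totals: np.ndarray
    records: pd.DataFrame

    @property
    def n_days(self) -> np.ndarray:
        return self.design.n_days

    def validate(self) -> None:
        if (self.removals < 0).any():
            raise ValueError("negative removals")
        if (self.effort < 0).any():
            raise ValueError("negative effort")
        if not np.array_equal(self.period_totals, self.removals.sum(axis=2)):
            raise ValueError("period_totals inconsistent with daily removals")
        unsampled = ~self.design.sampled_mask
        if self.period_totals[unsampled].any():
            raise ValueError("removals present outside sampled periods")


def ingest_records(records: pd.DataFrame, design: StudyDesign) -> RemovalSeries:
    """Bin daily removal records into model-ready arrays.

    Parameters
    ----------
    records
        One row per trapping day with columns ``date`` (ISO 8601),
        ``removals`` (non-negative integer) and ``traps`` (non-negative
        integer); an optional ``area`` column must contain a single
        value.  Rows outside the March--October analysis window are
        dropped before binning.  A day is *active* when ``traps > 0``;
        inactive days with zero removals are skipped, and removals on a
        day without traps are rejected as inconsistent.
    design
        Calendar from :func:`build_design`; returned with ``n_days`` and
        ``sampled_mask`` refreshed from the data.
    """
    df = records.copy()
    required = {"date", "removals", "traps"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if "area" in df.columns and df["area"].nunique() > 1:
        raise ValueError("records span multiple areas; ingest one area at a time")

    n_years = design.n_years
    max_days = 365 - (design.max_period - 1) * design.period_length
    removals = np.zeros((n_years, design.max_period, max_days), dtype=np.int64)
    traps_daily = np.zeros_like(removals)
    n_days = np.zeros((n_years, design.max_period), dtype=np.int64)
    effort = np.zeros((n_years, design.max_period), dtype=float)

    kept_rows = []
    if len(df):
        dates = pd.to_datetime(df["date"]).dt.date
        if dates.duplicated().any():
            dup = dates[dates.duplicated()].iloc[0]
            raise ValueError(f"duplicate date in records: {dup}")
        rem = df["removals"].to_numpy()
        trp = df["traps"].to_numpy()
        if (rem < 0).any() or (trp < 0).any():
            raise ValueError("negative removals or traps")
        if not (np.equal(np.mod(rem, 1), 0).all() and np.equal(np.mod(trp, 1), 0).all()):
            raise ValueError("removals and traps must be integers")

        order = np.argsort(dates.to_numpy())
        for i in order:
            date = dates.iloc[i]
            if date.year not in design.years:
                raise ValueError(f"date {date} outside design years {design.years}")
            if not (3 <= date.month <= 10):
                continue  # outside the March-October analysis window
            r, k = int(rem[i]), int(trp[i])
            if k == 0:
                if r > 0:
                    raise ValueError(f"removals recorded with zero traps on {date}")
                continue
            y = design.years.index(date.year)
            doy = _day_of_year_365(date)
            t = design.period_of_doy(doy)
            j = n_days[y, t - 1]  # active days take consecutive slots in date order
            removals[y, t - 1, j] = r
            traps_daily[y, t - 1, j] = k
            n_days[y, t - 1] = j + 1
            kept_rows.append(
                {"date": date.isoformat(), "year_idx": y, "period": t,
                 "day_idx": j + 1, "removals": r, "traps": k}
            )

    sampled = n_days > 0
    with np.errstate(invalid="ignore"):
        sums = traps_daily.sum(axis=2, dtype=float)
        effort[sampled] = sums[sampled] / n_days[sampled]

    new_design = dataclasses.replace(design, sampled_mask=sampled, n_days=n_days)
    rec_df = pd.DataFrame(
        kept_rows,
        columns=["date", "year_idx", "period", "day_idx", "removals", "traps"],
    )
    series = RemovalSeries(
        design=new_design,
        removals=removals,
        effort=effort,
        period_totals=removals.sum(axis=2),
        records=rec_df,
    )
    series.validate()
    return series


def export_records(series: RemovalSeries, area: str | None = None) -> pd.DataFrame:
    """Export a series back to the daily record layout (round-trippable)."""
    out = series.records[["date", "removals", "traps"]].copy()
    if area is not None:
        out["area"] = area
    return out
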