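"""ISO-8601 week calendar utilities.

All weekly aggregation in this package uses ISO-8601 weeks: weeks start on
Monday and week 1 of a year is the week containing that year's first
Thursday, so an ISO year has either 52 or 53 weeks. A week is identified by
the pair ``(iso_year, iso_week)``.

The follow-up week grid contains only the ISO weeks *fully contained* in the
follow-up interval, so a follow-up starting on a Saturday contributes its
first partial week's days to no week. Rates are converted from per
patient-week to per 100 patient-years with the mean number of weeks per
calendar year, 365.25/7 (~52.1786).
"""
from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

#: Mean ISO weeks per calendar year, used to convert weekly rates to
#: per-100-patient-year units.
WEEKS_PER_YEAR = 365.25 / 7

IsoWeek = tuple[int, int]


def monday(week: IsoWeek) -> dt.date:
    """First day (Monday) of an ISO week."""
    return dt.date.fromisocalendar(week[0], week[1], 1)


def sunday(week: IsoWeek) -> dt.date:
    """Last day (Sunday) of an ISO week."""
    return monday(week) + dt.timedelta(days=6)


def iso_week(d: dt.date) -> IsoWeek:
    """ISO (year, week) pair of a calendar date."""
    y, w, _ = d.isocalendar()
    return (y, w)


def n_weeks_in_year(iso_year: int) -> int:
    """Number of ISO weeks (52 or 53) in an ISO year."""
    # Dec 28 always falls in the last ISO week of its year.
    return dt.date(iso_year, 12, 28).isocalendar()[1]


def week_grid(start: dt.date, end: dt.date) -> list[IsoWeek]:
    """All ISO weeks fully contained in ``[start, end]``, in order.

    Raises
    ------
    ValueError
        If the interval is reversed or contains no full ISO week.
    """
    if end < start:
        raise ValueError(f"reversed interval: {start}..{end}")
    first = monday(iso_week(start))
    if first < start:
        first += dt.timedelta(days=7)
    grid: list[IsoWeek] = []
    m = first
    while m + dt.timedelta(days=6) <= end:
        grid.append(iso_week(m))
        m += dt.timedelta(days=7)
    if not grid:
        raise ValueError(f"interval {start}..{end} contains no full ISO week")
    return grid


def mondays_array(grid: list[IsoWeek]) -> np.ndarray:
    """Mondays of a week grid as a ``datetime64[D]`` array."""
    return np.array([monday(w) for w in grid], dtype="datetime64[D]")


def grid_frame(grid: list[IsoWeek]) -> pd.DataFrame:
    """Week grid as a DataFrame with columns iso_year, iso_week."""
    return pd.DataFrame(grid, columns=["iso_year", "iso_week"])


def is_year_end_week(week: IsoWeek) -> bool:
    """True if the week is the last ISO week of its ISO year.

    This is the week containing the Christmas/New Year period, in which
    primary-care recording activity drops.
    """
    return week[1] == n_weeks_in_year(week[0])
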