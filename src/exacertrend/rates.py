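"""Weekly exacerbation rates and quarterly aggregation.

The weekly rate is the number of episode weeks divided by the number of
patients active in the cohort that week, converted to episodes per 100
patient-years with the factor 365.25/7 (weeks per year) x 100. The
denominator varies week by week as patients leave the cohort (deregistration,
death, asthma resolution).

Follow-up is divided into consecutive 13-ISO-week quarters per calendar
year; an ISO year with 53 weeks contributes one 14-week final quarter that
absorbs week 53. Each quarter's summary is the unweighted arithmetic mean of
its constituent weekly rates with a two-tailed t-distribution 95% CI — not
pooled episodes over pooled patient-weeks, which differs under attrition.
"""
from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import weeks
from .exceptions import EmptyDenominatorError
from .weeks import WEEKS_PER_YEAR, IsoWeek

DENOMINATOR_CONVENTIONS = ("overlap", "strict")


@dataclass(frozen=True)
class Quarter:
    """A block of consecutive ISO weeks within one ISO year."""

    iso_year: int
    week_start: int
    week_end: int

    @property
    def position(self) -> int:
        """Quarter position 1-4 within the year, from the starting week."""
        return min((self.week_start - 1) // 13 + 1, 4)

    @property
    def weeks(self) -> tuple[IsoWeek, ...]:
        return tuple((self.iso_year, w) for w in range(self.week_start, self.week_end + 1))

    @property
    def n_weeks(self) -> int:
        return self.week_end - self.week_start + 1

    @property
    def label(self) -> str:
        return f"{self.iso_year} (weeks {self.week_start}-{self.week_end})"


def build_quarters(
    follow_up: tuple[dt.date, dt.date],
    quarter_map: list[tuple[int, int, int]] | None = None,
) -> list[Quarter]:
    """Quarter calendar over the follow-up week grid.

    Weeks are chunked into blocks of 13 within each ISO year; when a
    53-week ISO year would leave week 53 alone, the final block takes 14
    weeks. A trailing block shorter than 13 weeks is dropped with a warning
    naming the dropped weeks.

    An explicit ``quarter_map`` of ``(iso_year, week_start, week_end)``
    rows overrides the default chunking (for analyses that must match an
    externally fixed quarter calendar).
    """
    if quarter_map is not None:
        return [Quarter(*row) for row in quarter_map]
    grid = weeks.week_grid(*follow_up)
    quarters: list[Quarter] = []
    years = pd.unique(pd.Series([y for y, _ in grid]))
    for year in years:
        wknums = [w for y, w in grid if y == year]
        i = 0
        while len(wknums) - i >= 13:
            take = 13
            if len(wknums) - i == 14 and wknums[i + 13] == 53:
                take = 14
            quarters.append(Quarter(int(year), wknums[i], wknums[i + take - 1]))
            i += take
        if i < len(wknums):
            dropped = wknums[i:]
            warnings.warn(
                f"dropping {len(dropped)} trailing week(s) of ISO year {year} "
                f"that do not fill a quarter: weeks {dropped[0]}-{dropped[-1]}",
                stacklevel=2,
            )
    return quarters


def _interval_bounds(registry: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    starts = pd.to_datetime(registry["start_date"]).to_numpy(dtype="datetime64[D]")
    ends = pd.to_datetime(registry["end_date"]).to_numpy(dtype="datetime64[D]")
    return starts, ends


def active_patient_series(
    registry: pd.DataFrame,
    grid: list[IsoWeek],
    convention: str = "overlap",
) -> np.ndarray:
    """Active-patient count for every week of the grid.

    ``overlap`` (default): a patient counts in a week if their activity
    interval overlaps any day of it. ``strict``: the interval must cover
    the whole week.
    """
    if convention not in DENOMINATOR_CONVENTIONS:
        raise ValueError(f"unknown denominator convention {convention!r}")
    starts, ends = _interval_bounds(registry)
    mons = weeks.mondays_array(grid)
    suns = mons + np.timedelta64(6, "D")
    if convention == "overlap":
        mask = (starts[:, None] <= suns[None, :]) & (ends[:, None] >= mons[None, :])
    else:
        mask = (starts[:, None] <= mons[None, :]) & (ends[:, None] >= suns[None, :])
    return mask.sum(axis=0).astype(int)


def active_patients(
    registry: pd.DataFrame, week: IsoWeek, convention: str = "overlap"
) -> int:
    """Number of patients active in one ISO week."""
    return int(active_patient_series(registry, [week], convention)[0])


def weekly_rates(
    episodes: pd.DataFrame,
    registry: pd.DataFrame,
    follow_up: tuple[dt.date, dt.date],
    convention: str = "overlap",
) -> pd.DataFrame:
    """Weekly episode counts, denominators and rates over follow-up.

    Returns one row per ISO week fully contained in the follow-up interval,
    columns ``iso_year, iso_week, episodes, active_patients, rate`` (rate in
    episodes per 100 patient-years).

    Raises
    ------
    EmptyDenominatorError
        If any week has no active patient.
    """
    grid = weeks.week_grid(*follow_up)
    out = weeks.grid_frame(grid)
    if episodes.empty:
        counts = np.zeros(len(grid), dtype=int)
    else:
        per_week = episodes.groupby(["iso_year", "iso_week"]).size()
        counts = np.array(
            [int(per_week.get(w, 0)) for w in grid], dtype=int
        )
    active = active_patient_series(registry, grid, convention)
    if (active == 0).any():
        bad = [grid[i] for i in np.nonzero(active == 0)[0]]
        raise EmptyDenominatorError(
            f"empty denominator: no active patients in week(s) {bad[:5]}"
            + ("..." if len(bad) > 5 else "")
        )
    out["episodes"] = counts
    out["active_patients"] = active
    out["rate"] = counts / active * WEEKS_PER_YEAR * 100.0
    return out


def quarterly_mean(rates, confidence: float = 0.95) -> tuple[float, float, float]:
    """Mean of a quarter's weekly rates with a two-tailed t-interval.

    Returns ``(mean, lo, hi)`` where the CI is mean +/- t_{1-a/2, n-1} *
    sd/sqrt(n) with the sample standard deviation. Requires >= 2 weeks;
    identical rates give a degenerate interval (mean, mean).
    """
    r = np.asarray(rates, dtype=float)
    n = r.size
    if n < 2:
        raise ValueError(f"quarterly mean needs >=2 weekly rates, got {n}")
    m = float(r.mean())
    half = float(stats.t.ppf(0.5 + confidence / 2, n - 1) * r.std(ddof=1) / np.sqrt(n))
    return m, m - half, m + half


def quarterly_table(
    weekly: pd.DataFrame, quarters: list[Quarter]
) -> pd.DataFrame:
    """Quarterly summary of a weekly rate series.

    One row per quarter: year, week range, position, number of weeks,
    patients at the start of the quarter, total episodes, mean weekly rate
    and its 95% t-interval.
    """
    idx = weekly.set_index(["iso_year", "iso_week"])
    rows = []
    for q in quarters:
        sub = idx.loc[list(q.weeks)]
        mean, lo, hi = quarterly_mean(sub["rate"].to_numpy())
        rows.append(
            {
                "year": q.iso_year,
                "week_start": q.week_start,
                "week_end": q.week_end,
                "position": q.position,
                "n_weeks": q.n_weeks,
                "patients_at_start": int(sub["active_patients"].iloc[0]),
                "episodes": int(sub["episodes"].sum()),
                "rate": mean,
                "ci_lo": lo,
                "ci_hi": hi,
            }
        )
    return pd.DataFrame(rows)
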