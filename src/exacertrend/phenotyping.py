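"""Cohort identification and weekly exacerbation-episode ascertainment.

The asthma cohort is every patient with at least one asthma diagnosis code
recorded during the identification window (default 2010-2015). During
follow-up, each patient-week is classified as exacerbation / no
exacerbation: a week holds an episode if any of three triggers falls in it,

(a) an asthma-related A&E attendance code;
(b) a hospital-admission code with an asthma diagnosis code recorded for
    the same patient on the same day;
(c) an oral corticosteroid (OCS) prescription with a respiratory-review
    event within the review window (default 14 calendar days, symmetric).

The outcome is binary per patient-week: multiple triggers in one ISO week
collapse to a single episode; triggers in different weeks are distinct
episodes. Each episode week carries a care-setting label: ``hospital`` if
any trigger is (a) or (b) — the setting where the episode was resolved —
otherwise ``primary``.

Episode tables are plain DataFrames with columns
``patient_id, iso_year, iso_week, setting`` (one row per episode week).
"""
from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd

from . import weeks
from .codelists import Codelist, CodelistSet
from .exceptions import ConfigurationError, EmptyCohortError

logger = logging.getLogger(__name__)

EPISODE_COLUMNS = ["patient_id", "iso_year", "iso_week", "setting"]

#: Allowed values for the review-window direction: the review may be
#: required strictly after the prescription, strictly before, or either side.
REVIEW_MODES = ("after", "before", "both")


def _as_dates(s: pd.Series) -> pd.Series:
    return pd.to_datetime(s).dt.normalize()


def identify_cohort(
    events: pd.DataFrame,
    asthma_codelist: Codelist,
    id_window: tuple[dt.date, dt.date],
) -> set[int]:
    """Patients with >=1 asthma diagnosis code dated within ``id_window``.

    Idempotent; events outside the window or with other codes are ignored.
    """
    lo, hi = id_window
    if hi < lo:
        raise ConfigurationError(f"reversed identification window {lo}..{hi}")
    if events.empty:
        return set()
    dates = _as_dates(events["date"])
    mask = (
        events["code"].isin(asthma_codelist.codes)
        & (dates >= pd.Timestamp(lo))
        & (dates <= pd.Timestamp(hi))
    )
    return set(events.loc[mask, "patient_id"].unique().tolist())


def classify_setting(trigger_kinds) -> str:
    """Care setting of an episode week from its qualifying trigger kinds.

    ``hospital`` takes precedence: any A&E attendance or qualifying
    admission in the week labels the episode hospital-resolved, even if a
    qualifying OCS prescription also occurred.
    """
    kinds = set(trigger_kinds)
    if not kinds:
        raise ValueError("classify_setting requires at least one trigger")
    unknown = kinds - {"ae", "admission", "ocs"}
    if unknown:
        raise ValueError(f"unknown trigger kinds: {sorted(unknown)}")
    return "hospital" if kinds & {"ae", "admission"} else "primary"


def _qualifying_ocs(
    prescriptions: pd.DataFrame,
    reviews: pd.DataFrame,
    window_days: int,
    mode: str,
) -> pd.DataFrame:
    """OCS prescriptions with a respiratory review within the window."""
    if prescriptions.empty or reviews.empty:
        return prescriptions.iloc[0:0]
    ocs = prescriptions.sort_values("date", kind="stable")
    rev = reviews.sort_values("date", kind="stable")
    tol = pd.Timedelta(days=window_days)
    direction = {"after": "forward", "before": "backward", "both": "nearest"}[mode]
    merged = pd.merge_asof(
        ocs,
        rev[["patient_id", "date"]].rename(columns={"date": "review_date"}),
        left_on="date",
        right_on="review_date",
        by="patient_id",
        direction=direction,
        tolerance=tol,
    )
    return merged[merged["review_date"].notna()][["patient_id", "date"]]


def ascertain_episodes(
    events: pd.DataFrame,
    prescriptions: pd.DataFrame,
    codelists: CodelistSet,
    follow_up: tuple[dt.date, dt.date],
    review_window_days: int = 14,
    review_window_mode: str = "both",
) -> pd.DataFrame:
    """Classify every patient-week of follow-up, returning episode weeks.

    Records dated outside the follow-up interval, or in a partial ISO week
    at either end of it, are ignored (counted at debug level); so are codes
    that appear in no codelist. Row order of the inputs is irrelevant.

    Returns a DataFrame with one row per (patient, ISO week) that holds an
    episode, columns ``patient_id, iso_year, iso_week, setting``, sorted by
    patient then week.
    """
    if review_window_mode not in REVIEW_MODES:
        raise ConfigurationError(
            f"review_window_mode must be one of {REVIEW_MODES}, "
            f"got {review_window_mode!r}"
        )
    if review_window_days < 0:
        raise ConfigurationError("review_window_days must be >= 0")
    grid = weeks.week_grid(*follow_up)
    lo = pd.Timestamp(weeks.monday(grid[0]))
    hi = pd.Timestamp(weeks.sunday(grid[-1]))

    events = events.copy()
    prescriptions = prescriptions.copy()
    events["date"] = _as_dates(events["date"]) if len(events) else pd.Series([], dtype="datetime64[ns]")
    prescriptions["date"] = (
        _as_dates(prescriptions["date"]) if len(prescriptions) else pd.Series([], dtype="datetime64[ns]")
    )

    in_fu = (events["date"] >= lo) & (events["date"] <= hi)
    logger.debug("ignoring %d coded events outside follow-up", int((~in_fu).sum()))
    ev = events[in_fu]
    in_fu_rx = (prescriptions["date"] >= lo) & (prescriptions["date"] <= hi)
    logger.debug("ignoring %d prescriptions outside follow-up", int((~in_fu_rx).sum()))
    rx = prescriptions[in_fu_rx]

    # Rule (a): A&E attendance codes.
    ae = ev[ev["code"].isin(codelists["ae_attendance"].codes)][["patient_id", "date"]]

    # Rule (b): admission code with an asthma code the same day.
    adm = ev[ev["code"].isin(codelists["hospital_admission"].codes)][["patient_id", "date"]]
    asthma_days = ev[ev["code"].isin(codelists["asthma_diagnosis"].codes)][
        ["patient_id", "date"]
    ].drop_duplicates()
    adm = adm.merge(asthma_days, on=["patient_id", "date"], how="inner")

    # Rule (c): OCS prescription with respiratory review within the window.
    ocs = rx[rx["drug_class"].isin(codelists["ocs"].codes)][["patient_id", "date"]]
    reviews = ev[ev["code"].isin(codelists["respiratory_review"].codes)][
        ["patient_id", "date"]
    ]
    ocs_ok = _qualifying_ocs(ocs, reviews, review_window_days, review_window_mode)

    triggers = pd.concat(
        [ae.assign(kind="ae"), adm.assign(kind="admission"), ocs_ok.assign(kind="ocs")],
        ignore_index=True,
    )
    if triggers.empty:
        return pd.DataFrame(columns=EPISODE_COLUMNS)

    iso = triggers["date"].dt.isocalendar()
    triggers["iso_year"] = iso["year"].astype(int)
    triggers["iso_week"] = iso["week"].astype(int)
    # Drop triggers landing in partial boundary weeks outside the grid.
    grid_set = set(grid)
    in_grid = [
        (y, w) in grid_set
        for y, w in zip(triggers["iso_year"], triggers["iso_week"])
    ]
    triggers = triggers[np.asarray(in_grid, dtype=bool)]
    if triggers.empty:
        return pd.DataFrame(columns=EPISODE_COLUMNS)

    hospital = triggers["kind"].isin(["ae", "admission"])
    out = (
        triggers.assign(hospital=hospital)
        .groupby(["patient_id", "iso_year", "iso_week"], as_index=False)["hospital"]
        .any()
    )
    out["setting"] = np.where(out["hospital"], "hospital", "primary")
    return (
        out[EPISODE_COLUMNS]
        .sort_values(["patient_id", "iso_year", "iso_week"], kind="stable")
        .reset_index(drop=True)
    )


def restrict_to_exacerbators(episodes: pd.DataFrame, cohort: set[int]) -> set[int]:
    """Cohort members with at least one exacerbation episode in follow-up."""
    if episodes.empty:
        return set()
    return set(episodes["patient_id"].unique().tolist()) & set(cohort)


def require_nonempty_cohort(cohort: set[int]) -> set[int]:
    """Raise :class:`EmptyCohortError` if the analysis cohort is empty."""
    if not cohort:
        raise EmptyCohortError("empty analysis cohort: no patient had an episode")
    return cohort
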