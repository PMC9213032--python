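"""Stratification (sex, age group, region, care setting) and sensitivity cohorts.

Ages are approximated from year of birth by assuming a mid-year (July 1)
birthday and taking completed years at the reference date (default
2016-01-01, the start of follow-up). Age bands are 0-5, 6-17, 18-54 and
55+. Patients with a missing birth year or sex are excluded only from the
corresponding stratification, never from the overall analysis.

Region is inferred from the GP practice's postcode area through an
editable lookup table (individual-level location is not recorded).

Two sensitivity cohorts mirror the main analysis: *stayers* (patients still
active in the final quarter of follow-up, guarding against informative
attrition) and the *young* cohort (aged 34 or under at the start of
follow-up, excluding most asthma-COPD overlap).
"""
from __future__ import annotations

import datetime as dt
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .rates import Quarter
from . import weeks

logger = logging.getLogger(__name__)

AGE_GROUPS = ("0-5", "6-17", "18-54", "55+")
DEFAULT_REFERENCE_DATE = dt.date(2016, 1, 1)
STRATIFIERS = ("sex", "age", "region", "setting")


def age_at(birth_year: int, reference_date: dt.date) -> int:
    """Completed years at ``reference_date`` under the July-1 birthday rule."""
    if birth_year > reference_date.year:
        raise ConfigurationError(
            f"birth year {birth_year} is after reference date {reference_date}"
        )
    age = reference_date.year - birth_year
    if (reference_date.month, reference_date.day) < (7, 1):
        age -= 1
    # Born in the reference year before a mid-year reference date: age 0.
    return max(age, 0)


def assign_age_group(
    birth_year, reference_date: dt.date = DEFAULT_REFERENCE_DATE
) -> str | None:
    """Age band at the reference date, or None for a missing birth year."""
    if birth_year is None or (isinstance(birth_year, float) and np.isnan(birth_year)):
        return None
    a = age_at(int(birth_year), reference_date)
    if a <= 5:
        return AGE_GROUPS[0]
    if a <= 17:
        return AGE_GROUPS[1]
    if a <= 54:
        return AGE_GROUPS[2]
    return AGE_GROUPS[3]


def assign_age_groups(
    birth_years: pd.Series, reference_date: dt.date = DEFAULT_REFERENCE_DATE
) -> pd.Series:
    """Vectorised :func:`assign_age_group` over a birth-year column."""
    return birth_years.map(
        lambda by: assign_age_group(by, reference_date) if pd.notna(by) else None
    )


def load_region_lookup(path: str | Path | None = None) -> dict[str, str]:
    """Postcode-area -> region lookup from CSV (columns postcode_area,
    region); defaults to the editable table shipped with the package."""
    if path is None:
        with resources.as_file(
            resources.files("exacertrend.data") / "postcode_regions.csv"
        ) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return dict(zip(df["postcode_area"].astype(str), df["region"].astype(str)))


def assign_region(practice_postcode: str | None, lookup: dict[str, str]) -> str | None:
    """Region of a practice postcode via its leading postcode area.

    Unmapped areas yield None with a warning in the log.
    """
    if practice_postcode is None or (
        isinstance(practice_postcode, float) and np.isnan(practice_postcode)
    ):
        return None
    area = "".join(c for c in str(practice_postcode).strip().upper() if c.isalpha() or c.isdigit())
    # Postcode area = leading alphabetic characters of the outward code.
    letters = ""
    for c in area:
        if c.isalpha():
            letters += c
        else:
            break
    region = lookup.get(letters)
    if region is None:
        logger.warning("postcode area %r not in region lookup; region missing", letters)
    return region


def stratum_assignments(
    registry: pd.DataFrame,
    reference_date: dt.date = DEFAULT_REFERENCE_DATE,
) -> pd.DataFrame:
    """Per-patient stratum table: patient_id, sex, age_group, region."""
    out = registry[["patient_id"]].copy()
    out["sex"] = registry["sex"].where(registry["sex"].notna(), None) if "sex" in registry else None
    out["age_group"] = assign_age_groups(registry["birth_year"], reference_date)
    out["region"] = registry["region"].where(registry["region"].notna(), None) if "region" in registry else None
    return out


def strata_partition(
    registry: pd.DataFrame,
    by: str,
    reference_date: dt.date = DEFAULT_REFERENCE_DATE,
) -> dict[str, set[int]]:
    """Patient-id sets per stratum level for ``by`` in {sex, age, region}.

    Patients with the stratifier missing appear in no level.
    """
    if by not in ("sex", "age", "region"):
        raise ConfigurationError(f"cannot partition patients by {by!r}")
    assign = stratum_assignments(registry, reference_date)
    col = {"sex": "sex", "age": "age_group", "region": "region"}[by]
    out: dict[str, set[int]] = {}
    for level, grp in assign.dropna(subset=[col]).groupby(col):
        out[str(level)] = set(grp["patient_id"].tolist())
    return out


def sensitivity_cohorts(
    registry: pd.DataFrame,
    quarters: list[Quarter],
    reference_date: dt.date = DEFAULT_REFERENCE_DATE,
    age_cutoff: int = 34,
) -> tuple[set[int], set[int]]:
    """(stayers, young) sensitivity cohorts.

    Stayers are patients whose activity interval overlaps the final
    quarter of follow-up; the young cohort is patients aged ``age_cutoff``
    or under at the reference date (mid-year birthday rule).
    """
    final = quarters[-1]
    q_start = pd.Timestamp(weeks.monday(final.weeks[0]))
    q_end = pd.Timestamp(weeks.sunday(final.weeks[-1]))
    starts = pd.to_datetime(registry["start_date"])
    ends = pd.to_datetime(registry["end_date"])
    stay_mask = (starts <= q_end) & (ends >= q_start)
    stayers = set(registry.loc[stay_mask, "patient_id"].tolist())

    ages = registry["birth_year"].map(
        lambda by: age_at(int(by), reference_date) if pd.notna(by) else None
    )
    young_mask = ages.map(lambda a: a is not None and a <= age_cutoff)
    young = set(registry.loc[young_mask, "patient_id"].tolist())
    return stayers, young
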