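"""Published summary tables of the English OPCRD asthma-exacerbation cohort.

The patient-level database behind the original national analysis (OPCRD) is
licensed and cannot be redistributed, but its published quarterly summary —
patients at the start of each 13-week period, episode counts, and mean
weekly exacerbation rates per 100 patient-years with 95% CIs for
2016-2021 — and the published control-period comparison are shipped here as
small reference tables. They serve two purposes:

* internal-consistency checks (totals, control means and quarterly
  differences recomputed from the printed numbers);
* calibration of the synthetic cohort generator's defaults.
"""
from __future__ import annotations

import json
from importlib import resources

import pandas as pd


def _published(name: str):
    return resources.files("exacertrend.data") / "published" / name


def quarterly_summary() -> pd.DataFrame:
    """Published quarterly summary (2016-2021): one row per 13/14-week
    quarter with columns year, week_start, week_end, patients_at_start,
    episodes, rate, ci_lo, ci_hi."""
    with resources.as_file(_published("quarterly_rates_2016_2021.csv")) as p:
        df = pd.read_csv(p)
    df["quarter"] = (df["week_start"] - 1) // 13 + 1
    return df


def control_differences() -> pd.DataFrame:
    """Published 2020-2021 quarterly differences versus the 2016-2019
    control period (whole-cohort row): year, quarter, diff, pct_change,
    ci_lo, ci_hi (difference scale, per 100 patient-years)."""
    with resources.as_file(_published("control_period_differences.csv")) as p:
        return pd.read_csv(p)


def cohort_summary() -> dict[str, int]:
    """Published cohort-level counts (database size, cohort sizes,
    episode totals by care setting, sensitivity-cohort sizes)."""
    with resources.as_file(_published("cohort_summary.json")) as p:
        return json.loads(p.read_text())
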