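"""Figures: weekly rate time-series and quarterly control-period differences."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first
import matplotlib.pyplot as plt
import pandas as pd


def weekly_series(weekly: pd.DataFrame, ax=None):
    """Weekly exacerbation rate over follow-up (per 100 patient-years)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    x = range(len(weekly))
    ax.plot(x, weekly["rate"], lw=1.0)
    year_starts = weekly.index[weekly["iso_week"] == 1]
    ax.set_xticks(list(year_starts))
    ax.set_xticklabels(weekly.loc[year_starts, "iso_year"].astype(str))
    ax.set_ylabel("episodes per 100 patient-years")
    ax.set_xlabel("ISO week")
    ax.set_title("Weekly exacerbation rate")
    return ax


def quarterly_differences(comparisons: pd.DataFrame, ax=None):
    """Bar chart of quarterly differences vs the control period, with CIs."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    df = comparisons.reset_index(drop=True)
    labels = [f"{y} Q{q}" for y, q in zip(df["year"], df["quarter"])]
    err = [df["diff"] - df["ci_lo"], df["ci_hi"] - df["diff"]]
    ax.bar(labels, df["diff"], yerr=err, capsize=3, color="steelblue")
    ax.axhline(0, color="k", lw=0.8)
    ax.set_ylabel("difference vs control (per 100 patient-years)")
    ax.set_title("Quarterly change in exacerbation rate vs control period")
    ax.tick_params(axis="x", rotation=45)
    return ax
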