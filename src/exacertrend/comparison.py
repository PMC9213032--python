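"""Control-period construction and quarterly Welch comparisons.

The control time-series has one value per quarter position (1-4): the mean
of the corresponding quarterly rates over the pre-pandemic control years.
Each pandemic-period quarter is compared against its position-matched
control with

* the difference in mean weekly rate (episodes per 100 patient-years),
* a 95% CI from Welch's two-sample t-test (Satterthwaite degrees of
  freedom; no equal-variance assumption),
* the percentage change relative to the control mean.

The Welch samples are the target quarter's 13 weekly rates versus the
pooled weekly rates of the corresponding quarter position across all
control years (52 weeks for four 13-week control quarters); an alternative
mode uses the 4 quarterly means as the control sample. Reductions carry a
negative sign.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError
from .rates import Quarter

WELCH_SAMPLE_MODES = ("weekly", "quarterly")

#: Descriptive threshold (percent) above which a change is labelled
#: "substantial" in reports. A label, not an inferential gate.
SUBSTANTIAL_PCT = 25.0


@dataclass(frozen=True)
class PositionControl:
    """Control summary for one quarter position."""

    position: int
    control_mean: float                 # mean of the constituent quarterly means
    quarter_means: dict[int, float]     # control year -> quarterly mean rate
    pooled_rates: np.ndarray            # all constituent weekly rates


@dataclass
class ControlSeries:
    """Per-position control means with the weekly rates behind them."""

    control_years: tuple[int, ...]
    positions: dict[int, PositionControl] = field(default_factory=dict)

    def __getitem__(self, position: int) -> PositionControl:
        return self.positions[position]


@dataclass(frozen=True)
class QuarterComparison:
    """One pandemic-period quarter versus its position-matched control."""

    year: int
    position: int
    label: str
    target_mean: float
    control_mean: float
    diff: float
    ci_lo: float
    ci_hi: float
    pct_change: float
    welch_t: float
    welch_df: float

    @property
    def substantial(self) -> bool:
        return abs(self.pct_change) > SUBSTANTIAL_PCT


def control_series(
    weekly: pd.DataFrame,
    quarters: list[Quarter],
    control_years,
) -> ControlSeries:
    """Build the per-position control series from the weekly rate table.

    Every control year must contribute a quarter at every position present;
    a missing quarter raises a configuration error naming it.
    """
    control_years = tuple(int(y) for y in control_years)
    if len(control_years) < 2:
        raise ConfigurationError("control series needs >=2 control years")
    idx = weekly.set_index(["iso_year", "iso_week"])
    by_pos: dict[int, dict[int, np.ndarray]] = {}
    for q in quarters:
        if q.iso_year in control_years:
            rates = idx.loc[list(q.weeks), "rate"].to_numpy()
            by_pos.setdefault(q.position, {})[q.iso_year] = rates
    out = ControlSeries(control_years)
    for pos, per_year in sorted(by_pos.items()):
        missing = [y for y in control_years if y not in per_year]
        if missing:
            raise ConfigurationError(
                f"control year(s) {missing} lack a quarter at position {pos}"
            )
        qmeans = {y: float(r.mean()) for y, r in per_year.items()}
        out.positions[pos] = PositionControl(
            position=pos,
            control_mean=float(np.mean(list(qmeans.values()))),
            quarter_means=qmeans,
            pooled_rates=np.concatenate([per_year[y] for y in control_years]),
        )
    return out


def welch_ci(a, b, confidence: float = 0.95):
    """Welch two-sample comparison of means: ``(diff, lo, hi, t, df)``.

    ``diff = mean(a) - mean(b)`` with the Satterthwaite-approximation CI.
    If both samples are constant the CI degenerates to the point difference
    (with a warning) and t/df are NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch comparison needs >=2 values per sample")
    diff = float(a.mean() - b.mean())
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        warnings.warn("zero variance in both samples; degenerate Welch CI", stacklevel=2)
        return diff, diff, diff, float("nan"), float("nan")
    res = stats.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(confidence)
    return diff, float(ci.low), float(ci.high), float(res.statistic), float(res.df)


def compare_quarter(
    target_rates,
    control_rates,
    control_mean: float | None = None,
    *,
    year: int = 0,
    position: int = 0,
    label: str = "",
) -> QuarterComparison:
    """Compare one quarter's weekly rates with its pooled control rates.

    ``control_mean`` is the denominator for the percentage change (the mean
    of the control quarterly means); it defaults to the mean of
    ``control_rates``, which coincides when all control quarters have equal
    length.
    """
    target_rates = np.asarray(target_rates, dtype=float)
    control_rates = np.asarray(control_rates, dtype=float)
    diff, lo, hi, t, df = welch_ci(target_rates, control_rates)
    cmean = float(np.mean(control_rates)) if control_mean is None else float(control_mean)
    return QuarterComparison(
        year=year,
        position=position,
        label=label,
        target_mean=float(target_rates.mean()),
        control_mean=cmean,
        diff=diff,
        ci_lo=lo,
        ci_hi=hi,
        pct_change=100.0 * diff / cmean,
        welch_t=t,
        welch_df=df,
    )


def run_full_comparison(
    weekly: pd.DataFrame,
    quarters: list[Quarter],
    control_years,
    target_years,
    welch_samples: str = "weekly",
) -> list[QuarterComparison]:
    """One position-matched comparison per target-year quarter.

    The control and target spans must be disjoint. ``welch_samples``
    chooses the control sample: pooled weekly rates (default) or the
    control years' quarterly means.
    """
    if welch_samples not in WELCH_SAMPLE_MODES:
        raise ConfigurationError(f"welch_samples must be one of {WELCH_SAMPLE_MODES}")
    control_years = tuple(int(y) for y in control_years)
    target_years = tuple(int(y) for y in target_years)
    overlap = set(control_years) & set(target_years)
    if overlap:
        raise ConfigurationError(
            f"control and target spans overlap in year(s) {sorted(overlap)}"
        )
    ctrl = control_series(weekly, quarters, control_years)
    idx = weekly.set_index(["iso_year", "iso_week"])
    out: list[QuarterComparison] = []
    for q in quarters:
        if q.iso_year not in target_years:
            continue
        pc = ctrl[q.position]
        control_rates = (
            pc.pooled_rates
            if welch_samples == "weekly"
            else np.array(list(pc.quarter_means.values()))
        )
        out.append(
            compare_quarter(
                idx.loc[list(q.weeks), "rate"].to_numpy(),
                control_rates,
                control_mean=pc.control_mean,
                year=q.iso_year,
                position=q.position,
                label=q.label,
            )
        )
    return out


def comparisons_frame(comparisons: list[QuarterComparison]) -> pd.DataFrame:
    """Comparison list as a tidy DataFrame (one row per target quarter)."""
    return pd.DataFrame(
        [
            {
                "year": c.year,
                "quarter": c.position,
                "label": c.label,
                "target_mean": c.target_mean,
                "control_mean": c.control_mean,
                "diff": c.diff,
                "ci_lo": c.ci_lo,
                "ci_hi": c.ci_hi,
                "pct_change": c.pct_change,
                "welch_t": c.welch_t,
                "welch_df": c.welch_df,
                "substantial": c.substantial,
            }
            for c in comparisons
        ]
    )
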