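"""Simulation studies: estimator calibration against the generator's truth.

These studies close the loop between the synthetic generator and the
rate/comparison estimators:

* :func:`parameter_recovery` — inject a known step reduction in the
  exacerbation hazard at a cutover date and check that the percentage
  change implied by the latent truth falls inside the Welch 95% CI, and
  that the pooled point estimate is close to truth. The "truth" percentage
  change is computed from the simulated expected rates (so it accounts for
  seasonal alignment and attrition), not assumed equal to 100*(rho-1).
* :func:`ci_coverage` — check that the quarterly-mean t-intervals cover the
  simulation-truth quarterly rate at their nominal level. Run with zero
  seasonal amplitude, where the t-interval's exchangeable-weeks assumption
  holds exactly; with a within-quarter seasonal trend the interval is
  conservative by construction.
* :func:`flat_hazard_anova` / :func:`zero_multiplier_max_rate` — degenerate
  limits: a flat hazard shows no quarter-position effect, and a zero
  multiplier kills all post-cutover episodes.

Truth weekly tables are fed straight into the rate/comparison estimators,
bypassing record materialisation (record-level fidelity is checked
separately against a day-level brute-force oracle in the test suite).
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .comparison import compare_quarter, control_series
from .rates import Quarter, build_quarters
from .simulate import SimConfig, simulate_truth_weekly
from .weeks import WEEKS_PER_YEAR

#: Cutover used by the recovery study: the first Monday of 2020-Q2
#: (ISO week 2020-W14), so quarters are purely pre or post.
RECOVERY_CUTOVER = dt.date(2020, 3, 30)
CONTROL_YEARS = (2016, 2017, 2018, 2019)


def _derive_seeds(base_seed: int, n: int) -> np.ndarray:
    """Deterministic child seeds below 2**31."""
    return np.random.SeedSequence(base_seed).generate_state(n, dtype=np.uint32) % (2**31)


def _truth_rates(truth: pd.DataFrame) -> pd.DataFrame:
    """Weekly rate table (estimator input) from a truth weekly table."""
    out = truth[["iso_year", "iso_week", "active_patients"]].copy()
    out["episodes"] = truth["latent_episodes"]
    out["rate"] = (
        truth["latent_episodes"] / truth["active_patients"] * WEEKS_PER_YEAR * 100.0
    )
    return out


def _quarter_truth_mean(truth_idx: pd.DataFrame, q: Quarter) -> float:
    return float(truth_idx.loc[list(q.weeks), "expected_rate"].mean())


@dataclass
class RecoveryResult:
    per_quarter: pd.DataFrame   # label, coverage_pct, pooled_estimate, truth, abs_error
    n_runs: int

    @property
    def min_coverage_pct(self) -> float:
        return float(self.per_quarter["coverage_pct"].min())

    @property
    def max_abs_error(self) -> float:
        return float(self.per_quarter["abs_error"].max())


def parameter_recovery(
    n_runs: int = 100,
    n_patients: int = 20_000,
    rho: float = 0.6,
    base_seed: int = 1,
) -> RecoveryResult:
    """Recover an injected hazard multiplier through the full estimator.

    Simulates ``n_runs`` cohorts with a single multiplier ``rho`` applied
    from :data:`RECOVERY_CUTOVER`; for every post-cutover quarter, compares
    the pipeline's Welch CI (converted to the percentage scale) with the
    truth-derived percentage change of that run.
    """
    template = SimConfig(
        n_patients=n_patients,
        intervention_start=RECOVERY_CUTOVER,
        intervention_multipliers=(rho,),
    )
    quarters = build_quarters(template.follow_up)
    post = [q for q in quarters if q.weeks[0] >= (2020, 14)]
    labels = [q.label for q in post]
    covered = {lab: 0 for lab in labels}
    estimates: dict[str, list[float]] = {lab: [] for lab in labels}
    truths: dict[str, list[float]] = {lab: [] for lab in labels}

    for seed in _derive_seeds(base_seed, n_runs):
        cfg = template.replace(seed=int(seed))
        truth = simulate_truth_weekly(cfg)
        weekly = _truth_rates(truth)
        truth_idx = truth.set_index(["iso_year", "iso_week"])
        weekly_idx = weekly.set_index(["iso_year", "iso_week"])
        ctrl = control_series(weekly, quarters, CONTROL_YEARS)
        ctrl_quarters = {
            (q.iso_year, q.position): q for q in quarters if q.iso_year in CONTROL_YEARS
        }
        for q in post:
            pc = ctrl[q.position]
            comp = compare_quarter(
                weekly_idx.loc[list(q.weeks), "rate"].to_numpy(),
                pc.pooled_rates,
                control_mean=pc.control_mean,
                year=q.iso_year,
                position=q.position,
                label=q.label,
            )
            truth_target = _quarter_truth_mean(truth_idx, q)
            truth_control = float(
                np.mean(
                    [
                        _quarter_truth_mean(truth_idx, ctrl_quarters[(y, q.position)])
                        for y in CONTROL_YEARS
                    ]
                )
            )
            truth_pct = 100.0 * (truth_target - truth_control) / truth_control
            lo_pct = 100.0 * comp.ci_lo / comp.control_mean
            hi_pct = 100.0 * comp.ci_hi / comp.control_mean
            if lo_pct <= truth_pct <= hi_pct:
                covered[q.label] += 1
            estimates[q.label].append(comp.pct_change)
            truths[q.label].append(truth_pct)

    rows = []
    for lab in labels:
        pooled = float(np.mean(estimates[lab]))
        tr = float(np.mean(truths[lab]))
        rows.append(
            {
                "label": lab,
                "coverage_pct": 100.0 * covered[lab] / n_runs,
                "pooled_estimate": pooled,
                "truth": tr,
                "abs_error": abs(pooled - tr),
            }
        )
    return RecoveryResult(pd.DataFrame(rows), n_runs)


def ci_coverage(
    n_quarters: int = 200,
    n_patients: int = 2_000,
    base_seed: int = 2,
) -> float:
    """Empirical coverage (percent) of the quarterly-mean 95% t-interval.

    Simulated under zero seasonal amplitude and no intervention, so the
    weekly rates within a quarter are exchangeable and the nominal t
    coverage applies; truth is each run's expected quarterly rate.
    """
    template = SimConfig(
        n_patients=n_patients,
        seasonal_amplitude=0.0,
        intervention_start=None,
        intervention_multipliers=(),
    )
    quarters = [
        q for q in build_quarters(template.follow_up) if q.iso_year in CONTROL_YEARS
    ]
    per_run = len(quarters)
    n_runs = int(np.ceil(n_quarters / per_run))
    hits = total = 0
    from .rates import quarterly_mean  # local import to avoid cycle at module load

    for seed in _derive_seeds(base_seed, n_runs):
        truth = simulate_truth_weekly(template.replace(seed=int(seed)))
        weekly = _truth_rates(truth).set_index(["iso_year", "iso_week"])
        truth_idx = truth.set_index(["iso_year", "iso_week"])
        for q in quarters:
            if total >= n_quarters:
                break
            _, lo, hi = quarterly_mean(weekly.loc[list(q.weeks), "rate"].to_numpy())
            tr = _quarter_truth_mean(truth_idx, q)
            hits += int(lo <= tr <= hi)
            total += 1
    return 100.0 * hits / total


def flat_hazard_anova(n_patients: int = 5_000, seed: int = 3) -> float:
    """One-way ANOVA p-value for a quarter-position effect under A=0.

    With a flat hazard there is no seasonality, so grouping the
    pre-intervention weekly rates by quarter position should show no
    effect (large p-value).
    """
    cfg = SimConfig(
        n_patients=n_patients,
        seed=seed,
        seasonal_amplitude=0.0,
        intervention_start=None,
        intervention_multipliers=(),
    )
    truth = simulate_truth_weekly(cfg)
    weekly = _truth_rates(truth).set_index(["iso_year", "iso_week"])
    groups = []
    for pos in (1, 2, 3, 4):
        qs = [
            q
            for q in build_quarters(cfg.follow_up)
            if q.iso_year in CONTROL_YEARS and q.position == pos
        ]
        groups.append(
            np.concatenate([weekly.loc[list(q.weeks), "rate"].to_numpy() for q in qs])
        )
    return float(stats.f_oneway(*groups).pvalue)


def zero_multiplier_max_rate(n_patients: int = 2_000, seed: int = 4) -> float:
    """Maximum weekly rate after a cutover with multiplier 0 (must be 0)."""
    cfg = SimConfig(
        n_patients=n_patients,
        seed=seed,
        intervention_start=RECOVERY_CUTOVER,
        intervention_multipliers=(0.0,),
    )
    truth = simulate_truth_weekly(cfg)
    weekly = _truth_rates(truth)
    cut = pd.Timestamp(RECOVERY_CUTOVER)
    mondays = pd.to_datetime(
        [dt.date.fromisocalendar(y, w, 1) for y, w in zip(weekly["iso_year"], weekly["iso_week"])]
    )
    return float(weekly.loc[mondays >= cut, "rate"].max())
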