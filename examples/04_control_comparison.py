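"""Compare pandemic-period quarters against the pre-pandemic control series.

The control value for quarter position q is the mean of the 2016-2019
rates at that position; each 2020-2021 quarter is compared with Welch's
two-sample t-test on the weekly rates (13 target weeks vs the pooled
control weeks at the same position).
"""
from exacertrend import SimConfig, build_quarters, bundled_codelists, simulate, weekly_rates
from exacertrend.comparison import comparisons_frame, run_full_comparison
from exacertrend.phenotyping import ascertain_episodes, identify_cohort, restrict_to_exacerbators

cfg = SimConfig(n_patients=2_000, seed=7)
tables = simulate(cfg)
codelists = bundled_codelists()
cohort = identify_cohort(tables.events, codelists["asthma_diagnosis"], cfg.id_window)
episodes = ascertain_episodes(tables.events, tables.prescriptions, codelists, cfg.follow_up)
ids = restrict_to_exacerbators(episodes, cohort)
episodes = episodes[episodes["patient_id"].isin(ids)]
registry = tables.registry[tables.registry["patient_id"].isin(ids)]

weekly = weekly_rates(episodes, registry, cfg.follow_up)
quarters = build_quarters(cfg.follow_up)
comps = comparisons_frame(
    run_full_comparison(weekly, quarters, (2016, 2017, 2018, 2019), (2020, 2021))
)

cols = ["label", "diff", "ci_lo", "ci_hi", "pct_change", "substantial"]
print(comps[cols].round(1).to_string(index=False))
# diff is in episodes per 100 patient-years (negative = reduction vs the
# 2016-2019 control); pct_change is relative to the control mean; a change
# beyond +/-25% is flagged substantial. With the default intervention
# multipliers the reductions deepen to ~-60% in early 2021, mirroring the
# pattern the generator was calibrated to.
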