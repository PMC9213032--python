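"""Weekly rates, denominators, quarter calendar and t-intervals."""
import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from exacertrend import rates
from exacertrend.exceptions import EmptyDenominatorError
from exacertrend.simulate import SimConfig, simulate_registry, simulate_truth_weekly
from exacertrend.weeks import WEEKS_PER_YEAR


def registry_frame(rows):
    return pd.DataFrame(rows, columns=["patient_id", "start_date", "end_date"])


def episodes_frame(rows):
    return pd.DataFrame(rows, columns=["patient_id", "iso_year", "iso_week", "setting"])


class TestActivePatients:
    def test_full_coverage_counts_everyone(self):
        reg = registry_frame([(i, "2018-01-01", "2018-12-31") for i in range(10)])
        assert rates.active_patients(reg, (2018, 20)) == 10

    def test_midweek_end_counted_under_overlap_not_strict(self):
        # Week 2018-W20 runs Mon 14 May - Sun 20 May; one patient ends
        # Wednesday 16 May, one before the week, one covers it.
        reg = registry_frame(
            [
                (1, "2018-01-01", "2018-05-16"),
                (2, "2018-01-01", "2018-05-01"),
                (3, "2018-01-01", "2018-12-31"),
            ]
        )
        assert rates.active_patients(reg, (2018, 20), "overlap") == 2
        assert rates.active_patients(reg, (2018, 20), "strict") == 1

    def test_week_after_all_end_raises_empty_denominator(self):
        reg = registry_frame([(1, "2018-01-01", "2018-03-01")])
        with pytest.raises(EmptyDenominatorError, match="empty denominator"):
            rates.weekly_rates(
                episodes_frame([]), reg, (dt.date(2018, 1, 1), dt.date(2018, 12, 30))
            )


class TestWeeklyRates:
    def test_direct_formula(self):
        reg = registry_frame([(i, "2018-05-14", "2018-05-20") for i in range(1000)])
        eps = episodes_frame([(i, 2018, 20, "primary") for i in range(10)])
        out = rates.weekly_rates(eps, reg, (dt.date(2018, 5, 14), dt.date(2018, 5, 20)))
        assert len(out) == 1
        assert out.loc[0, "rate"] == pytest.approx(10 / 1000 * WEEKS_PER_YEAR * 100)
        assert round(out.loc[0, "rate"], 2) == 52.18

    def test_zero_episodes_zero_rate(self):
        reg = registry_frame([(1, "2018-05-14", "2018-05-20")])
        out = rates.weekly_rates(
            episodes_frame([]), reg, (dt.date(2018, 5, 14), dt.date(2018, 5, 20))
        )
        assert (out["rate"] == 0).all()

    def test_scale_equivariance_under_patient_duplication(self, small_tables, small_cfg):
        reg = small_tables.registry
        truth = small_tables.truth_patient_week
        eps = truth[truth["latent_episode"]].assign(setting="primary")[
            ["patient_id", "iso_year", "iso_week", "setting"]
        ]
        w1 = rates.weekly_rates(eps, reg, small_cfg.follow_up)
        reg2 = pd.concat(
            [reg, reg.assign(patient_id=reg["patient_id"] + 10_000)], ignore_index=True
        )
        eps2 = pd.concat(
            [eps, eps.assign(patient_id=eps["patient_id"] + 10_000)], ignore_index=True
        )
        w2 = rates.weekly_rates(eps2, reg2, small_cfg.follow_up)
        np.testing.assert_allclose(w1["rate"], w2["rate"])

    def test_monotone_attrition_in_simulation(self):
        reg = simulate_registry(SimConfig(n_patients=500, seed=3))
        grid_counts = rates.active_patient_series(
            reg, __import__("exacertrend").weeks.week_grid(dt.date(2016, 1, 2), dt.date(2021, 10, 3))
        )
        assert (np.diff(grid_counts) <= 0).all()

    def test_sex_stratum_additivity_per_week(self, small_tables, small_cfg):
        reg = small_tables.registry
        truth = small_tables.truth_patient_week
        eps = truth[truth["latent_episode"]].assign(setting="primary")[
            ["patient_id", "iso_year", "iso_week", "setting"]
        ]
        total = rates.weekly_rates(eps, reg, small_cfg.follow_up)
        parts = []
        for level in ("F", "M", None):
            ids = set(reg.loc[reg["sex"].isna() if level is None else reg["sex"] == level, "patient_id"])
            sub = rates.weekly_rates(
                eps[eps["patient_id"].isin(ids)],
                reg[reg["patient_id"].isin(ids)],
                small_cfg.follow_up,
            )
            parts.append(sub[["episodes", "active_patients"]])
        summed = sum(p.to_numpy() for p in parts)
        np.testing.assert_array_equal(summed, total[["episodes", "active_patients"]].to_numpy())

    def test_constant_hazard_rate_matches_lambda(self):
        # Flat hazard, no strata, no intervention: time-averaged weekly rate
        # stays inside the Monte-Carlo band around lambda0*52.1786*100.
        lam = 0.012
        means = []
        for seed in range(20):
            cfg = SimConfig(
                n_patients=400, seed=40 + seed, baseline_hazard=lam,
                seasonal_amplitude=0.0, intervention_start=None,
                intervention_multipliers=(), sex_effects={}, age_effects={},
            )
            truth = simulate_truth_weekly(cfg)
            means.append(
                (truth["latent_episodes"] / truth["active_patients"]).mean()
                * WEEKS_PER_YEAR * 100
            )
        p = 1 - np.exp(-lam)
        expected = p * WEEKS_PER_YEAR * 100
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - expected) < 3 * se + 0.3


class TestQuarterCalendar:
    def test_2016_has_four_13_week_quarters(self):
        qs = rates.build_quarters((dt.date(2016, 1, 4), dt.date(2017, 1, 1)))
        assert [(q.week_start, q.week_end) for q in qs] == [
            (1, 13), (14, 26), (27, 39), (40, 52)
        ]
        assert [q.position for q in qs] == [1, 2, 3, 4]

    def test_53_week_year_gets_14_week_final_quarter(self):
        qs = rates.build_quarters((dt.date(2019, 12, 30), dt.date(2021, 1, 3)))
        final = qs[-1]
        assert (final.iso_year, final.week_start, final.week_end) == (2020, 40, 53)
        assert final.n_weeks == 14
        assert final.position == 4

    def test_trailing_partial_block_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropping 7 trailing week"):
            qs = rates.build_quarters((dt.date(2018, 1, 1), dt.date(2018, 5, 20)))
        assert len(qs) == 1 and qs[0].n_weeks == 13

    def test_explicit_quarter_map_overrides(self):
        qs = rates.build_quarters(
            (dt.date(2016, 1, 4), dt.date(2017, 1, 1)),
            quarter_map=[(2016, 1, 13), (2016, 14, 26)],
        )
        assert len(qs) == 2
        assert qs[0].label == "2016 (weeks 1-13)"

    def test_study_span_has_23_quarters(self):
        qs = rates.build_quarters((dt.date(2016, 1, 2), dt.date(2021, 10, 3)))
        assert len(qs) == 23
        assert sum(q.n_weeks for q in qs) == 300
        assert qs[-1].label == "2021 (weeks 27-39)"


class TestQuarterlyMean:
    def test_identical_rates_give_degenerate_interval(self):
        m, lo, hi = rates.quarterly_mean([42.0] * 13)
        assert (m, lo, hi) == (42.0, 42.0, 42.0)

    def test_two_point_closed_form(self):
        # mean 55, sd sqrt(50); half-width t_{0.975,1}*sd/sqrt(2) = 63.5310
        m, lo, hi = rates.quarterly_mean([50.0, 60.0])
        assert m == pytest.approx(55.0)
        assert lo == pytest.approx(55.0 - 12.706204736 * np.sqrt(50) / np.sqrt(2), abs=1e-6)
        assert hi == pytest.approx(55.0 + 63.531023682, abs=1e-6)

    def test_single_week_rejected(self):
        with pytest.raises(ValueError):
            rates.quarterly_mean([50.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 200, allow_nan=False), min_size=2, max_size=14)
    )
    def test_interval_brackets_mean(self, values):
        m, lo, hi = rates.quarterly_mean(values)
        assert lo <= m <= hi
        assert m == pytest.approx(np.mean(values))
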