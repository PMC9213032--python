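"""Cohort identification and episode-ascertainment rules."""
import datetime as dt

import numpy as np
import pandas as pd
import pytest

from exacertrend import phenotyping as ph
from exacertrend.exceptions import EmptyCohortError
from exacertrend.simulate import SimConfig, simulate

from oracles import bruteforce_episodes

FOLLOW_UP = (dt.date(2016, 1, 2), dt.date(2021, 10, 3))
ID_WINDOW = (dt.date(2010, 1, 1), dt.date(2015, 12, 31))


def ev(*rows):
    return pd.DataFrame(rows, columns=["patient_id", "date", "code"])


def rx(*rows):
    return pd.DataFrame(rows, columns=["patient_id", "date", "drug_class"])


EMPTY_EV = pd.DataFrame(columns=["patient_id", "date", "code"])
EMPTY_RX = pd.DataFrame(columns=["patient_id", "date", "drug_class"])


class TestIdentifyCohort:
    def test_in_window_code_included_outside_excluded(self, codelists):
        events = ev(
            (1, "2012-06-01", "H33.."),   # inside window
            (2, "2016-03-01", "H33.."),   # after window
            (3, "2012-06-01", "66YJ."),   # wrong code
        )
        cohort = ph.identify_cohort(events, codelists["asthma_diagnosis"], ID_WINDOW)
        assert cohort == {1}

    def test_hand_enumerated_toy_cohort(self, codelists):
        # 10 patients, 4 with in-window asthma codes.
        rows = [(i, "2013-05-05", "H33..") for i in (1, 3, 5, 7)]
        rows += [(i, "2016-05-05", "H33..") for i in (2, 4)]
        rows += [(i, "2013-05-05", "663m.") for i in (6, 8, 9, 10)]
        cohort = ph.identify_cohort(ev(*rows), codelists["asthma_diagnosis"], ID_WINDOW)
        assert cohort == {1, 3, 5, 7}
        # idempotent
        assert ph.identify_cohort(ev(*rows), codelists["asthma_diagnosis"], ID_WINDOW) == cohort


class TestAscertainment:
    def test_ocs_with_review_within_two_weeks(self, codelists):
        events = ev((1, "2018-03-12", "66YJ."))
        rxs = rx((1, "2018-03-05", "ocs_prednisolone"))
        out = ph.ascertain_episodes(events, rxs, codelists, FOLLOW_UP)
        assert out.to_records(index=False).tolist() == [(1, 2018, 10, "primary")]

    def test_ocs_without_review_is_not_an_episode(self, codelists):
        rxs = rx((1, "2018-03-05", "ocs_prednisolone"))
        out = ph.ascertain_episodes(EMPTY_EV, rxs, codelists, FOLLOW_UP)
        assert out.empty

    def test_review_outside_window_rejected(self, codelists):
        events = ev((1, "2018-03-20", "66YJ."))  # 15 days after
        rxs = rx((1, "2018-03-05", "ocs_prednisolone"))
        out = ph.ascertain_episodes(events, rxs, codelists, FOLLOW_UP)
        assert out.empty

    @pytest.mark.parametrize(
        "mode,review_date,expected",
        [
            ("after", "2018-03-12", 1),
            ("after", "2018-02-26", 0),   # review precedes OCS
            ("before", "2018-02-26", 1),
            ("before", "2018-03-12", 0),
            ("both", "2018-02-26", 1),
        ],
    )
    def test_review_window_direction_modes(self, codelists, mode, review_date, expected):
        events = ev((1, review_date, "66YJ."))
        rxs = rx((1, "2018-03-05", "ocs_prednisolone"))
        out = ph.ascertain_episodes(
            events, rxs, codelists, FOLLOW_UP, review_window_mode=mode
        )
        assert len(out) == expected

    def test_admission_needs_same_day_asthma_code(self, codelists):
        alone = ev((1, "2019-11-02", "8H2P."))
        out = ph.ascertain_episodes(alone, EMPTY_RX, codelists, FOLLOW_UP)
        assert out.empty
        paired = ev((1, "2019-11-02", "8H2P."), (1, "2019-11-02", "H33.."))
        out = ph.ascertain_episodes(paired, EMPTY_RX, codelists, FOLLOW_UP)
        assert out.to_records(index=False).tolist() == [(1, 2019, 44, "hospital")]

    def test_mixed_triggers_one_week_collapse_to_hospital(self, codelists):
        # Admission + asthma code on 2019-11-02 and a qualifying OCS the
        # same ISO week give exactly one hospital episode.
        events = ev(
            (1, "2019-11-02", "8H2P."),
            (1, "2019-11-02", "H33.."),
            (1, "2019-11-05", "66YJ."),
        )
        rxs = rx((1, "2019-10-30", "ocs_prednisolone"))
        out = ph.ascertain_episodes(events, rxs, codelists, FOLLOW_UP)
        assert out.to_records(index=False).tolist() == [(1, 2019, 44, "hospital")]

    def test_triggers_in_different_weeks_are_distinct_episodes(self, codelists):
        events = ev((1, "2018-05-02", "663m."), (1, "2018-05-09", "663m."))
        out = ph.ascertain_episodes(events, EMPTY_EV.rename(columns={"code": "drug_class"}), codelists, FOLLOW_UP)
        assert len(out) == 2

    def test_events_outside_follow_up_ignored(self, codelists):
        events = ev((1, "2015-06-01", "663m."), (1, "2022-06-01", "663m."))
        out = ph.ascertain_episodes(events, EMPTY_RX, codelists, FOLLOW_UP)
        assert out.empty

    def test_duplicate_trigger_never_changes_counts(self, codelists):
        events = ev((1, "2018-05-02", "663m."))
        base = ph.ascertain_episodes(events, EMPTY_RX, codelists, FOLLOW_UP)
        doubled = ph.ascertain_episodes(
            pd.concat([events, events]), EMPTY_RX, codelists, FOLLOW_UP
        )
        pd.testing.assert_frame_equal(base, doubled)

    def test_row_order_invariance(self, codelists, small_tables):
        rng = np.random.default_rng(0)
        ev_shuf = small_tables.events.sample(frac=1, random_state=rng.integers(2**31))
        rx_shuf = small_tables.prescriptions.sample(frac=1, random_state=rng.integers(2**31))
        a = ph.ascertain_episodes(
            small_tables.events, small_tables.prescriptions, codelists, FOLLOW_UP
        )
        b = ph.ascertain_episodes(ev_shuf, rx_shuf, codelists, FOLLOW_UP)
        pd.testing.assert_frame_equal(a, b)


class TestClassifySetting:
    @pytest.mark.parametrize(
        "kinds,expected",
        [
            (["ocs"], "primary"),
            (["ae"], "hospital"),
            (["ocs", "admission"], "hospital"),
            (["ocs", "ae", "admission"], "hospital"),
        ],
    )
    def test_hospital_precedence(self, kinds, expected):
        assert ph.classify_setting(kinds) == expected

    def test_empty_or_unknown_rejected(self):
        with pytest.raises(ValueError):
            ph.classify_setting([])
        with pytest.raises(ValueError):
            ph.classify_setting(["telephone"])


class TestExacerbators:
    def test_subset_of_cohort(self, codelists):
        events = ev((1, "2018-05-02", "663m."), (9, "2018-05-02", "663m."))
        eps = ph.ascertain_episodes(events, EMPTY_RX, codelists, FOLLOW_UP)
        assert ph.restrict_to_exacerbators(eps, {1, 2, 3}) == {1}

    def test_empty_cohort_raises_downstream(self):
        with pytest.raises(EmptyCohortError, match="empty analysis cohort"):
            ph.require_nonempty_cohort(set())

    def test_exacerbator_fraction_monotone_in_baseline_hazard(self, codelists):
        fractions = []
        for lam in (0.004, 0.012, 0.03):
            cfg = SimConfig(n_patients=400, seed=21, baseline_hazard=lam)
            tab = simulate(cfg, patient_week_truth=False)
            eps = ph.ascertain_episodes(
                tab.events, tab.prescriptions, codelists, cfg.follow_up
            )
            cohort = ph.identify_cohort(
                tab.events, codelists["asthma_diagnosis"], cfg.id_window
            )
            frac = len(ph.restrict_to_exacerbators(eps, cohort)) / len(cohort)
            assert 0.0 < frac < 1.0
            fractions.append(frac)
        assert fractions == sorted(fractions)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_day_level_brute_force(self, codelists, seed):
        """Vectorised weekly classifier == day-by-day re-derivation."""
        cfg = SimConfig(n_patients=15, seed=100 + seed, baseline_hazard=0.03,
                        ocs_no_review_rate=0.01, review_lag_max=20)
        tab = simulate(cfg, patient_week_truth=False)
        got = ph.ascertain_episodes(
            tab.events, tab.prescriptions, codelists, cfg.follow_up
        )
        got_tuples = [tuple(r) for r in got.to_records(index=False)]
        expected = bruteforce_episodes(
            tab.events, tab.prescriptions, codelists, cfg.follow_up
        )
        assert got_tuples == expected

    def test_setting_partition_sums_to_total(self, codelists, small_tables, small_cfg):
        eps = ph.ascertain_episodes(
            small_tables.events, small_tables.prescriptions, codelists, small_cfg.follow_up
        )
        counts = eps["setting"].value_counts()
        assert counts.get("primary", 0) + counts.get("hospital", 0) == len(eps)
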