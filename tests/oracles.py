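"""Independent brute-force oracles used by the test suite.

These re-derive expected results by direct day-level enumeration with plain
Python loops, deliberately sharing no code path with the vectorised
implementation they check.
"""
from __future__ import annotations

import datetime as dt
import math

import pandas as pd


def bruteforce_episodes(
    events: pd.DataFrame,
    prescriptions: pd.DataFrame,
    codelists,
    follow_up: tuple[dt.date, dt.date],
    review_window_days: int = 14,
    review_window_mode: str = "both",
) -> list[tuple[int, int, int, str]]:
    """Day-by-day re-derivation of the weekly episode classification.

    Returns sorted tuples ``(patient_id, iso_year, iso_week, setting)``.
    """
    ae = codelists["ae_attendance"].codes
    adm = codelists["hospital_admission"].codes
    asthma = codelists["asthma_diagnosis"].codes
    review = codelists["respiratory_review"].codes
    ocs = codelists["ocs"].codes

    # Week grid: ISO weeks fully inside follow-up.
    lo, hi = follow_up
    first = dt.date.fromisocalendar(*lo.isocalendar()[:2], 1)
    if first < lo:
        first += dt.timedelta(days=7)
    allowed_weeks = set()
    m = first
    while m + dt.timedelta(days=6) <= hi:
        allowed_weeks.add(m.isocalendar()[:2])
        m += dt.timedelta(days=7)
    day_lo = first
    day_hi = max(allowed_weeks_last := m - dt.timedelta(days=1), first)

    def in_follow_up(d: dt.date) -> bool:
        return day_lo <= d <= day_hi

    ev_by_patient: dict[int, list[tuple[dt.date, str]]] = {}
    for row in events.itertuples(index=False):
        d = pd.Timestamp(row.date).date()
        ev_by_patient.setdefault(int(row.patient_id), []).append((d, str(row.code)))
    rx_by_patient: dict[int, list[tuple[dt.date, str]]] = {}
    for row in prescriptions.itertuples(index=False):
        d = pd.Timestamp(row.date).date()
        rx_by_patient.setdefault(int(row.patient_id), []).append(
            (d, str(row.drug_class))
        )

    out = []
    for patient in sorted(set(ev_by_patient) | set(rx_by_patient)):
        evs = [(d, c) for d, c in ev_by_patient.get(patient, []) if in_follow_up(d)]
        rxs = [(d, c) for d, c in rx_by_patient.get(patient, []) if in_follow_up(d)]
        review_days = [d for d, c in evs if c in review]
        asthma_days = {d for d, c in evs if c in asthma}
        triggers: list[tuple[dt.date, str]] = []
        for d, c in evs:
            if c in ae:
                triggers.append((d, "hospital"))
            if c in adm and d in asthma_days:
                triggers.append((d, "hospital"))
        for d, c in rxs:
            if c not in ocs:
                continue
            for r in review_days:
                delta = (r - d).days
                if review_window_mode == "after" and not 0 <= delta <= review_window_days:
                    continue
                if review_window_mode == "before" and not -review_window_days <= delta <= 0:
                    continue
                if review_window_mode == "both" and abs(delta) > review_window_days:
                    continue
                triggers.append((d, "primary"))
                break
        weeks_hit: dict[tuple[int, int], set[str]] = {}
        for d, kind in triggers:
            wk = d.isocalendar()[:2]
            if wk in allowed_weeks:
                weeks_hit.setdefault(wk, set()).add(kind)
        for (y, w), kinds in weeks_hit.items():
            out.append((patient, y, w, "hospital" if "hospital" in kinds else "primary"))
    return sorted(out)


def welch_closed_form(a, b, confidence: float = 0.95):
    """Hand-coded Welch statistic, Satterthwaite df and CI.

    Uses only ``statistics``-level arithmetic plus the t quantile.
    """
    from scipy.stats import t as tdist

    def mean(x):
        return sum(x) / len(x)

    def var(x):
        m = mean(x)
        return sum((v - m) ** 2 for v in x) / (len(x) - 1)

    n1, n2 = len(a), len(b)
    v1, v2 = var(a), var(b)
    diff = mean(a) - mean(b)
    se2 = v1 / n1 + v2 / n2
    se = math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    tq = tdist.ppf(0.5 + confidence / 2, df)
    return diff, diff - tq * se, diff + tq * se, diff / se, df
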