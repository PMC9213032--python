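"""Synthetic primary-care EHR generator for asthma-exacerbation analyses.

Real UK primary-care repositories (e.g. OPCRD) are licensed and cannot be
redistributed, so every downstream stage of this package is exercised on
synthetic registry/event/prescription tables that reproduce the statistical
structure the analysis assumes:

* a weekly Bernoulli exacerbation process per active patient, with hazard
  lambda0 * s(w) * g_i * I(w): a cosine seasonal factor s(w) peaking in
  winter (period 365.25/7 weeks, so the phase does not drift over a
  multi-year follow-up), patient strata effects g_i (sex, age band,
  region), and a step intervention factor I(w) that multiplies the hazard
  by per-quarter factors from a cutover date (emulating pandemic-period
  suppression of exacerbations);
* non-informative attrition: each patient's follow-up ends after a
  geometric number of weeks with per-week dropout hazard mu, censored at
  the follow-up end;
* episode materialisation: each latent episode resolves in hospital with
  probability pi_h (emitting an A&E-attendance code, or an admission code
  plus a same-day asthma code) and otherwise in primary care (an OCS
  prescription plus a respiratory-review event lagged 0..review_lag_max
  days);
* coding noise: non-qualifying OCS prescriptions without review, and a
  recording dip in the year-end ISO week (restricted practice opening over
  Christmas) where an episode's records are only written with probability
  delta.

The generator also returns the latent truth (per-week expected rates and,
optionally, the full patient-week indicator table) so that estimator
recovery can be tested against known parameters.

At most one latent episode can occur per patient-week, matching the binary
patient-week outcome definition used by the ascertainment stage.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import strata, weeks
from .codelists import bundled_codelists
from .exceptions import ConfigurationError
from .rates import build_quarters
from .weeks import WEEKS_PER_YEAR

__all__ = ["SimConfig", "SyntheticTables", "simulate_registry", "simulate_events",
           "simulate_truth_weekly"]


def _default_region_weights() -> dict[str, float]:
    # Regional mix of the published English cohort.
    return {
        "East England": 21326,
        "East Midlands": 4911,
        "London": 3179,
        "North East": 4988,
        "North West": 11910,
        "South East": 19975,
        "South West": 14691,
        "West Midlands": 2124,
        "Yorkshire and the Humber": 17258,
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the published English asthma-exacerbator cohort
    (n=100,362 followed 2016-2021): baseline hazard calibrated to the
    pre-pandemic mean rate of ~66 episodes per 100 patient-years, winter
    seasonal peak, dropout hazard matching the observed attrition from
    100,362 to 58,776 patients over 299 weeks, 11.8% of episodes resolved
    in hospital, and per-quarter intervention multipliers matching the
    observed pandemic-period reductions from 2020-03-23.
    """

    n_patients: int = 100_362
    seed: int = 0
    follow_up_start: dt.date = dt.date(2016, 1, 2)
    follow_up_end: dt.date = dt.date(2021, 10, 3)
    id_window_start: dt.date = dt.date(2010, 1, 1)
    id_window_end: dt.date = dt.date(2015, 12, 31)

    #: Expected episodes per patient-week for a reference (unit strata
    #: factor) patient at the seasonal midpoint, before any intervention.
    #: Calibrated so that, under the default strata mix and effects (mean
    #: factor ~1.037), the cohort-mean pre-pandemic rate is ~66 episodes
    #: per 100 patient-years.
    baseline_hazard: float = 0.01224
    #: Fractional seasonal swing in [0, 1); hazard peaks at (1+A)*lambda0.
    seasonal_amplitude: float = 0.25
    #: ISO week number at which the seasonal factor is maximal.
    peak_week: int = 1
    #: Date from which the intervention multipliers apply (None: never).
    intervention_start: dt.date | None = dt.date(2020, 3, 23)
    #: Hazard multipliers for successive quarters from the quarter
    #: containing the intervention date onwards; the last value persists to
    #: the end of follow-up. The default cutover (2020-03-23) falls in the
    #: last week of 2020-Q1, hence the leading near-unity value.
    intervention_multipliers: tuple[float, ...] = (0.92, 0.60, 0.53, 0.44, 0.37, 0.42, 0.47)
    #: Per-week dropout probability (non-informative attrition).
    dropout_hazard: float = 0.00179
    #: Fraction of episodes resolved in hospital.
    hospital_fraction: float = 0.118
    #: Among hospital episodes, fraction recorded as A&E attendance
    #: (the rest are admissions with a same-day asthma code).
    ae_fraction: float = 0.7
    #: Per-patient-week probability of a non-qualifying OCS prescription
    #: (no respiratory review).
    ocs_no_review_rate: float = 0.002
    #: Review lag for primary-care episodes, uniform on {0..review_lag_max}
    #: days; values above the 14-day ascertainment window exercise the
    #: rule's rejection branch.
    review_lag_max: int = 14
    #: Probability that records of a year-end-week episode are written at
    #: all (Christmas recording dip). 1 disables the dip.
    christmas_dip: float = 0.5

    # Population mix (remainders are recorded as missing).
    sex_probs: dict[str, float] = field(
        default_factory=lambda: {"F": 0.598, "M": 0.388}
    )
    age_group_probs: dict[str, float] = field(
        default_factory=lambda: {"0-5": 0.0137, "6-17": 0.1043, "18-54": 0.4385, "55+": 0.4420}
    )
    region_weights: dict[str, float] = field(default_factory=_default_region_weights)

    # Multiplicative hazard effects per stratum (missing level -> 1.0).
    sex_effects: dict[str, float] = field(
        default_factory=lambda: {"F": 1.1, "M": 0.9}
    )
    age_effects: dict[str, float] = field(
        default_factory=lambda: {"0-5": 1.3, "6-17": 0.9, "18-54": 0.95, "55+": 1.1}
    )
    region_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        if self.seed < 0:
            raise ConfigurationError("seed must be non-negative")
        if self.follow_up_end <= self.follow_up_start:
            raise ConfigurationError("follow_up_end must be after follow_up_start")
        for name in ("dropout_hazard", "hospital_fraction", "ae_fraction",
                     "ocs_no_review_rate", "christmas_dip"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.seasonal_amplitude < 1.0:
            raise ConfigurationError("seasonal_amplitude must be in [0, 1)")
        if not 1 <= self.peak_week <= 53:
            raise ConfigurationError("peak_week must be an ISO week number 1..53")
        if self.review_lag_max < 0:
            raise ConfigurationError("review_lag_max must be >= 0")
        for m in self.intervention_multipliers:
            if not 0.0 <= m <= 1.0:
                raise ConfigurationError(f"intervention multiplier {m} outside [0, 1]")
        if self.intervention_start is not None and not (
            self.follow_up_start <= self.intervention_start <= self.follow_up_end
        ):
            raise ConfigurationError("intervention_start outside follow-up")
        for name, probs in (("sex_probs", self.sex_probs),
                            ("age_group_probs", self.age_group_probs)):
            total = sum(probs.values())
            if any(p < 0 for p in probs.values()) or total > 1.0 + 1e-9:
                raise ConfigurationError(f"{name} must be non-negative and sum to <=1")
        # Weekly hazard must stay below ~one expected episode per week for
        # every stratum, otherwise the Bernoulli approximation is meaningless.
        smax, sarg = max(
            ((v, k) for k, v in {**{"": 1.0}, **self.sex_effects}.items())
        )
        amax, aarg = max(
            ((v, k) for k, v in {**{"": 1.0}, **self.age_effects}.items())
        )
        rmax, rarg = max(
            ((v, k) for k, v in {**{"": 1.0}, **self.region_effects}.items())
        )
        peak = self.baseline_hazard * (1 + self.seasonal_amplitude) * smax * amax * rmax
        if peak >= 1.0:
            raise ConfigurationError(
                "peak weekly hazard >= 1 episode/week for stratum "
                f"(sex={sarg or 'any'}, age={aarg or 'any'}, region={rarg or 'any'}): "
                f"lambda0*(1+A)*g = {peak:.3f}"
            )

    # -- derived quantities ---------------------------------------------
    @property
    def follow_up(self) -> tuple[dt.date, dt.date]:
        return (self.follow_up_start, self.follow_up_end)

    @property
    def id_window(self) -> tuple[dt.date, dt.date]:
        return (self.id_window_start, self.id_window_end)

    @property
    def reference_date(self) -> dt.date:
        """Reference date for age assignment: Jan 1 of the follow-up year."""
        return dt.date(self.follow_up_start.year, 1, 1)

    def replace(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        kwargs = dict(d)
        for key in ("follow_up_start", "follow_up_end", "id_window_start",
                    "id_window_end", "intervention_start"):
            if key in kwargs and isinstance(kwargs[key], str):
                kwargs[key] = dt.date.fromisoformat(kwargs[key])
        if "intervention_multipliers" in kwargs and kwargs["intervention_multipliers"] is not None:
            kwargs["intervention_multipliers"] = tuple(kwargs["intervention_multipliers"])
        return cls(**kwargs)


@dataclass
class SyntheticTables:
    """Generator output: input tables for the pipeline plus latent truth."""

    registry: pd.DataFrame
    events: pd.DataFrame
    prescriptions: pd.DataFrame
    truth_weekly: pd.DataFrame
    truth_patient_week: pd.DataFrame | None = None

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [
            ("registry", self.registry),
            ("events", self.events),
            ("prescriptions", self.prescriptions),
            ("truth", self.truth_weekly),
        ]:
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        if self.truth_patient_week is not None:
            p = outdir / "truth_patient_week.csv"
            self.truth_patient_week.to_csv(p, index=False)
            paths["truth_patient_week"] = p
        return paths


# ---------------------------------------------------------------------------
# random streams: registry and event materialisation draw from separate
# children of the config seed, so simulate_registry / simulate_events are
# individually reproducible.

def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def simulate_registry(cfg: SimConfig) -> pd.DataFrame:
    """Patient registry: id, birth year, sex, region, activity interval.

    Activity starts at the follow-up start for every patient; the end is
    drawn from a geometric dropout process with per-week hazard mu,
    censored at the follow-up end. Byte-identical under a fixed seed.
    """
    rng = _rng(cfg, 0)
    n = cfg.n_patients
    grid = weeks.week_grid(*cfg.follow_up)
    W = len(grid)
    monday0 = weeks.monday(grid[0])

    sex_levels = sorted(cfg.sex_probs)
    sex_p = [cfg.sex_probs[k] for k in sex_levels] + [1 - sum(cfg.sex_probs.values())]
    sex = rng.choice(np.array(sex_levels + [None], dtype=object), size=n, p=sex_p)

    ref_year = cfg.reference_date.year
    # Mid-year birthday rule: age at Jan 1 of the reference year is
    # ref_year - 1 - birth_year.
    band_birth_range = {
        "0-5": (ref_year - 6, ref_year - 1),
        "6-17": (ref_year - 18, ref_year - 7),
        "18-54": (ref_year - 55, ref_year - 19),
        "55+": (ref_year - 96, ref_year - 56),
    }
    age_levels = sorted(cfg.age_group_probs)
    age_p = [cfg.age_group_probs[k] for k in age_levels] + [
        1 - sum(cfg.age_group_probs.values())
    ]
    bands = rng.choice(np.array(age_levels + [None], dtype=object), size=n, p=age_p)
    birth_year = np.full(n, np.nan)
    for band in age_levels:
        mask = bands == band
        lo, hi = band_birth_range[band]
        birth_year[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))

    region_levels = sorted(cfg.region_weights)
    rw = np.array([cfg.region_weights[k] for k in region_levels], dtype=float)
    region = rng.choice(np.array(region_levels, dtype=object), size=n, p=rw / rw.sum())

    if cfg.dropout_hazard == 0.0:
        active_weeks = np.full(n, W)
    else:
        active_weeks = np.minimum(rng.geometric(cfg.dropout_hazard, size=n), W)
    end = np.array(monday0, dtype="datetime64[D]") + (active_weeks * 7 - 1).astype(
        "timedelta64[D]"
    )
    end = np.minimum(end, np.datetime64(cfg.follow_up_end, "D"))

    return pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1, dtype=np.int64),
            "birth_year": pd.array(
                [int(b) if not np.isnan(b) else pd.NA for b in birth_year],
                dtype="Int64",
            ),
            "sex": sex,
            "region": region,
            "start_date": pd.Timestamp(cfg.follow_up_start),
            "end_date": pd.to_datetime(end),
        }
    )


def _strata_factors(cfg: SimConfig, registry: pd.DataFrame) -> np.ndarray:
    age_groups = strata.assign_age_groups(registry["birth_year"], cfg.reference_date)
    g = np.ones(len(registry))
    g *= registry["sex"].map(lambda s: cfg.sex_effects.get(s, 1.0)).to_numpy(float)
    g *= age_groups.map(lambda a: cfg.age_effects.get(a, 1.0)).to_numpy(float)
    g *= registry["region"].map(lambda r: cfg.region_effects.get(r, 1.0)).to_numpy(float)
    return g


def _week_multipliers(cfg: SimConfig, grid: list) -> np.ndarray:
    """Intervention factor I(w) for every grid week."""
    W = len(grid)
    I = np.ones(W)
    if cfg.intervention_start is None or not cfg.intervention_multipliers:
        return I
    mondays = weeks.mondays_array(grid)
    post = mondays >= np.datetime64(cfg.intervention_start, "D")
    if not post.any():
        return I
    quarters = build_quarters(cfg.follow_up)
    week_to_q = {w: qi for qi, q in enumerate(quarters) for w in q.weeks}
    first_post_q = min(
        (week_to_q[grid[i]] for i in np.nonzero(post)[0] if grid[i] in week_to_q),
        default=None,
    )
    mult = np.asarray(cfg.intervention_multipliers)
    for i in np.nonzero(post)[0]:
        qi = week_to_q.get(grid[i])
        k = len(mult) - 1 if qi is None or first_post_q is None else min(
            qi - first_post_q, len(mult) - 1
        )
        I[i] = mult[k]
    return I


def _latent_process(cfg: SimConfig, registry: pd.DataFrame, rng: np.random.Generator):
    """Shared latent simulation: active mask, episode probabilities and draws."""
    grid = weeks.week_grid(*cfg.follow_up)
    W = len(grid)
    monday0 = np.datetime64(weeks.monday(grid[0]), "D")
    starts = pd.to_datetime(registry["start_date"]).to_numpy(dtype="datetime64[D]")
    ends = pd.to_datetime(registry["end_date"]).to_numpy(dtype="datetime64[D]")
    first_w = np.maximum(((starts - monday0).astype(int)) // 7, 0)
    last_w = np.minimum(((ends - monday0).astype(int)) // 7, W - 1)
    wk = np.arange(W)
    active = (wk[None, :] >= first_w[:, None]) & (wk[None, :] <= last_w[:, None])

    t0 = next((i for i, w in enumerate(grid) if w[1] == cfg.peak_week), 0)
    s = 1.0 + cfg.seasonal_amplitude * np.cos(2 * np.pi * (wk - t0) / WEEKS_PER_YEAR)
    I = _week_multipliers(cfg, grid)
    g = _strata_factors(cfg, registry)

    lam = cfg.baseline_hazard * np.outer(g, s * I)
    if lam.max() >= 1.0:
        i, w = np.unravel_index(int(lam.argmax()), lam.shape)
        raise ConfigurationError(
            f"weekly hazard >= 1 for patient {registry['patient_id'].iloc[i]} "
            f"(sex={registry['sex'].iloc[i]}, region={registry['region'].iloc[i]}) "
            f"in week {grid[w]}"
        )
    p = 1.0 - np.exp(-lam)
    latent = (rng.random(p.shape) < p) & active
    return grid, active, p, latent, s, I


def _truth_weekly_frame(grid, active, p, latent, s, I) -> pd.DataFrame:
    n_active = active.sum(axis=0)
    with np.errstate(invalid="ignore"):
        expected_rate = np.where(
            n_active > 0,
            (p * active).sum(axis=0) / np.maximum(n_active, 1) * WEEKS_PER_YEAR * 100.0,
            np.nan,
        )
    out = weeks.grid_frame(grid)
    out["active_patients"] = n_active.astype(int)
    out["latent_episodes"] = latent.sum(axis=0).astype(int)
    out["expected_rate"] = expected_rate
    out["seasonal_factor"] = s
    out["intervention_factor"] = I
    return out


def simulate_truth_weekly(cfg: SimConfig) -> pd.DataFrame:
    """Fast path: only the latent process, summarised per week.

    Returns the per-week truth table (active patients, latent episode
    counts, expected rate per 100 patient-years, seasonal and intervention
    factors) without materialising coded records. Identical latent draws to
    :func:`simulate_events` under the same config.
    """
    registry = simulate_registry(cfg)
    rng = _rng(cfg, 1)
    grid, active, p, latent, s, I = _latent_process(cfg, registry, rng)
    return _truth_weekly_frame(grid, active, p, latent, s, I)


def simulate_events(
    registry: pd.DataFrame,
    cfg: SimConfig,
    patient_week_truth: bool = True,
) -> SyntheticTables:
    """Materialise coded events and prescriptions from the latent process.

    Every patient receives one asthma diagnosis code at a uniform date in
    the identification window (so the phenotyping stage can rediscover the
    cohort). Each latent episode emits either hospital-type records or an
    OCS prescription plus lagged review; see the module docstring for the
    noise model.
    """
    rng = _rng(cfg, 1)
    grid, active, p, latent, s, I = _latent_process(cfg, registry, rng)
    mondays = weeks.mondays_array(grid)
    year_end = np.array([weeks.is_year_end_week(w) for w in grid])
    cl = bundled_codelists()
    asthma_codes = sorted(cl["asthma_diagnosis"].codes)
    ae_codes = sorted(cl["ae_attendance"].codes)
    adm_codes = sorted(cl["hospital_admission"].codes)
    review_codes = sorted(cl["respiratory_review"].codes)
    ocs_classes = sorted(cl["ocs"].codes)
    pid = registry["patient_id"].to_numpy()
    ends = pd.to_datetime(registry["end_date"]).to_numpy(dtype="datetime64[D]")

    ev_pid, ev_date, ev_code = [], [], []
    rx_pid, rx_date, rx_class = [], [], []

    def emit_event(pids, dates, codes):
        ev_pid.append(pids)
        ev_date.append(dates)
        ev_code.append(codes)

    # Cohort-defining asthma codes in the identification window.
    id_lo = np.datetime64(cfg.id_window_start, "D")
    id_days = (np.datetime64(cfg.id_window_end, "D") - id_lo).astype(int) + 1
    emit_event(
        pid,
        id_lo + rng.integers(0, id_days, size=len(pid)).astype("timedelta64[D]"),
        rng.choice(asthma_codes, size=len(pid)),
    )

    ii, ww = np.nonzero(latent)
    m = len(ii)
    if m:
        day = rng.integers(0, 7, size=m).astype("timedelta64[D]")
        dates = mondays[ww] + day
        hospital = rng.random(m) < cfg.hospital_fraction
        ae = hospital & (rng.random(m) < cfg.ae_fraction)
        adm = hospital & ~ae
        lag = rng.integers(0, cfg.review_lag_max + 1, size=m).astype("timedelta64[D]")
        # Christmas recording dip: the whole episode's records are only
        # written with probability delta in the year-end ISO week.
        recorded = ~year_end[ww] | (rng.random(m) < cfg.christmas_dip)

        k = ae & recorded
        emit_event(pid[ii[k]], dates[k], rng.choice(ae_codes, size=int(k.sum())))
        k = adm & recorded
        emit_event(pid[ii[k]], dates[k], rng.choice(adm_codes, size=int(k.sum())))
        emit_event(pid[ii[k]], dates[k], rng.choice(asthma_codes, size=int(k.sum())))
        k = ~hospital & recorded
        rx_pid.append(pid[ii[k]])
        rx_date.append(dates[k])
        rx_class.append(rng.choice(ocs_classes, size=int(k.sum())))
        # A review scheduled after the patient's deregistration never
        # happens: the prescription then stays non-qualifying.
        review_dates = dates[k] + lag[k]
        held = review_dates <= ends[ii[k]]
        emit_event(
            pid[ii[k]][held],
            review_dates[held],
            rng.choice(review_codes, size=int(held.sum())),
        )

    # Non-qualifying OCS prescriptions (no review), with the same
    # recording dip in the year-end week.
    if cfg.ocs_no_review_rate > 0:
        noise = (rng.random(active.shape) < cfg.ocs_no_review_rate) & active
        ni, nw = np.nonzero(noise)
        if len(ni):
            nd = mondays[nw] + rng.integers(0, 7, size=len(ni)).astype("timedelta64[D]")
            keep = ~year_end[nw] | (rng.random(len(ni)) < cfg.christmas_dip)
            rx_pid.append(pid[ni[keep]])
            rx_date.append(nd[keep])
            rx_class.append(rng.choice(ocs_classes, size=int(keep.sum())))

    events = pd.DataFrame(
        {
            "patient_id": np.concatenate(ev_pid),
            "date": pd.to_datetime(np.concatenate(ev_date)),
            "code": np.concatenate(ev_code),
        }
    ).sort_values(["patient_id", "date", "code"], kind="stable", ignore_index=True)
    if rx_pid:
        prescriptions = pd.DataFrame(
            {
                "patient_id": np.concatenate(rx_pid),
                "date": pd.to_datetime(np.concatenate(rx_date)),
                "drug_class": np.concatenate(rx_class),
            }
        ).sort_values(["patient_id", "date", "drug_class"], kind="stable", ignore_index=True)
    else:
        prescriptions = pd.DataFrame(
            {"patient_id": pd.Series(dtype=np.int64),
             "date": pd.Series(dtype="datetime64[ns]"),
             "drug_class": pd.Series(dtype=object)}
        )

    truth_weekly = _truth_weekly_frame(grid, active, p, latent, s, I)
    truth_pw = None
    if patient_week_truth:
        ai, aw = np.nonzero(active)
        grid_years = np.array([y for y, _ in grid], dtype=np.int32)
        grid_weeks = np.array([w for _, w in grid], dtype=np.int16)
        truth_pw = pd.DataFrame(
            {
                "patient_id": pid[ai],
                "iso_year": grid_years[aw],
                "iso_week": grid_weeks[aw],
                "latent_episode": latent[ai, aw],
            }
        )
    return SyntheticTables(registry, events, prescriptions, truth_weekly, truth_pw)


def simulate(cfg: SimConfig, patient_week_truth: bool = True) -> SyntheticTables:
    """Convenience wrapper: registry + events in one call."""
    return simulate_events(simulate_registry(cfg), cfg, patient_week_truth)
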