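"""End-to-end run configuration and orchestration.

``RunConfig`` collects everything a full analysis needs — input table and
codelist paths, the identification window, follow-up interval, review
window, control/target spans, stratifications and sensitivity cohorts —
and is validated before any computation. :func:`run_pipeline` executes
phenotyping -> rates -> comparison (plus stratified and sensitivity
reruns), writes all outputs as CSV with a JSON run manifest, and returns
the in-memory results.
"""
from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .codelists import load_codelists
from .comparison import comparisons_frame, run_full_comparison
from .exceptions import ConfigurationError
from .phenotyping import (
    ascertain_episodes,
    identify_cohort,
    require_nonempty_cohort,
    restrict_to_exacerbators,
)
from .rates import build_quarters, quarterly_table, weekly_rates
from .strata import (
    sensitivity_cohorts,
    strata_partition,
    stratum_assignments,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one full analysis run."""

    registry: Path
    events: Path
    prescriptions: Path
    codelists: Path
    outdir: Path
    follow_up_start: dt.date = dt.date(2016, 1, 2)
    follow_up_end: dt.date = dt.date(2021, 10, 3)
    id_window_start: dt.date = dt.date(2010, 1, 1)
    id_window_end: dt.date = dt.date(2015, 12, 31)
    review_window_days: int = 14
    review_window_mode: str = "both"
    denominator: str = "overlap"
    welch_samples: str = "weekly"
    control_years: tuple[int, ...] = (2016, 2017, 2018, 2019)
    target_years: tuple[int, ...] = (2020, 2021)
    stratify: tuple[str, ...] = ()
    sensitivity: tuple[str, ...] = ()
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("registry", "events", "prescriptions", "codelists", "outdir"):
            setattr(self, name, Path(getattr(self, name)))
        for name in ("control_years", "target_years", "stratify", "sensitivity"):
            setattr(self, name, tuple(getattr(self, name)))
        self.validate()

    def validate(self) -> None:
        for name in ("registry", "events", "prescriptions", "codelists"):
            p = getattr(self, name)
            if not p.exists():
                raise ConfigurationError(f"{name} path does not exist: {p}")
        if self.follow_up_end <= self.follow_up_start:
            raise ConfigurationError("follow-up span is reversed")
        if self.id_window_end <= self.id_window_start:
            raise ConfigurationError("identification window is reversed")
        overlap = set(self.control_years) & set(self.target_years)
        if overlap:
            raise ConfigurationError(
                f"control and target spans overlap in year(s) {sorted(overlap)}"
            )
        bad = set(self.stratify) - {"sex", "age", "region", "setting"}
        if bad:
            raise ConfigurationError(f"unknown stratifier(s) {sorted(bad)}")
        bad = set(self.sensitivity) - {"stayers", "young"}
        if bad:
            raise ConfigurationError(f"unknown sensitivity cohort(s) {sorted(bad)}")

    @property
    def follow_up(self) -> tuple[dt.date, dt.date]:
        return (self.follow_up_start, self.follow_up_end)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("follow_up_start", "follow_up_end", "id_window_start", "id_window_end"):
            if key in raw and isinstance(raw[key], str):
                raw[key] = dt.date.fromisoformat(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: str(v) if isinstance(v, (Path, dt.date)) else v for k, v in d.items()}

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _read_table(path: Path, date_cols: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in date_cols:
        df[c] = pd.to_datetime(df[c])
    return df


def _analysis_for_patients(
    cfg: RunConfig, episodes: pd.DataFrame, registry: pd.DataFrame, patient_ids: set[int]
):
    """Rates, quarterly table and comparisons for a patient subset."""
    reg = registry[registry["patient_id"].isin(patient_ids)]
    eps = episodes[episodes["patient_id"].isin(patient_ids)]
    weekly = weekly_rates(eps, reg, cfg.follow_up, cfg.denominator)
    quarters = build_quarters(cfg.follow_up)
    quarterly = quarterly_table(weekly, quarters)
    comps = comparisons_frame(
        run_full_comparison(
            weekly, quarters, cfg.control_years, cfg.target_years, cfg.welch_samples
        )
    )
    return weekly, quarterly, comps


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Outputs under ``cfg.outdir``: episodes.csv, weekly_rates.csv,
    quarterly_rates.csv, comparisons.csv (one block per stratum, with an
    ``all`` row set), strata.csv, manifest.json. Returns the DataFrames
    keyed by the same names.
    """
    logging.basicConfig(level=cfg.log_level)
    registry = _read_table(cfg.registry, ["start_date", "end_date"])
    events = _read_table(cfg.events, ["date"])
    prescriptions = _read_table(cfg.prescriptions, ["date"])
    codelists = load_codelists(cfg.codelists)
    codelists.require(
        "asthma_diagnosis", "ae_attendance", "hospital_admission",
        "respiratory_review", "ocs",
    )

    cohort = identify_cohort(
        events, codelists["asthma_diagnosis"], (cfg.id_window_start, cfg.id_window_end)
    )
    logger.info("identified asthma cohort: %d patients", len(cohort))
    episodes = ascertain_episodes(
        events,
        prescriptions,
        codelists,
        cfg.follow_up,
        cfg.review_window_days,
        cfg.review_window_mode,
    )
    episodes = episodes[episodes["patient_id"].isin(cohort)]
    analysis_cohort = require_nonempty_cohort(
        restrict_to_exacerbators(episodes, cohort)
    )
    logger.info("analysis cohort (>=1 episode): %d patients", len(analysis_cohort))
    episodes = episodes[episodes["patient_id"].isin(analysis_cohort)]
    registry = registry[registry["patient_id"].isin(analysis_cohort)]

    weekly, quarterly, comps = _analysis_for_patients(
        cfg, episodes, registry, analysis_cohort
    )
    comps.insert(0, "stratifier", "all")
    comps.insert(1, "stratum", "all")
    all_comps = [comps]

    for by in cfg.stratify:
        if by == "setting":
            for setting in ("primary", "hospital"):
                eps = episodes[episodes["setting"] == setting]
                w = weekly_rates(eps, registry, cfg.follow_up, cfg.denominator)
                c = comparisons_frame(
                    run_full_comparison(
                        w, build_quarters(cfg.follow_up),
                        cfg.control_years, cfg.target_years, cfg.welch_samples,
                    )
                )
                c.insert(0, "stratifier", "setting")
                c.insert(1, "stratum", setting)
                all_comps.append(c)
        else:
            for level, ids in strata_partition(registry, by).items():
                ids &= analysis_cohort
                if not ids:
                    continue
                _, _, c = _analysis_for_patients(cfg, episodes, registry, ids)
                c.insert(0, "stratifier", by)
                c.insert(1, "stratum", level)
                all_comps.append(c)

    if cfg.sensitivity:
        quarters = build_quarters(cfg.follow_up)
        stayers, young = sensitivity_cohorts(registry, quarters)
        for name, ids in (("stayers", stayers), ("young", young)):
            if name not in cfg.sensitivity:
                continue
            ids &= analysis_cohort
            _, _, c = _analysis_for_patients(cfg, episodes, registry, ids)
            c.insert(0, "stratifier", "sensitivity")
            c.insert(1, "stratum", name)
            all_comps.append(c)

    comparisons = pd.concat(all_comps, ignore_index=True)
    assignments = stratum_assignments(registry)

    cfg.outdir.mkdir(parents=True, exist_ok=True)
    outputs = {
        "episodes": episodes,
        "weekly_rates": weekly,
        "quarterly_rates": quarterly,
        "comparisons": comparisons,
        "strata": assignments,
    }
    for name, df in outputs.items():
        df.to_csv(cfg.outdir / f"{name}.csv", index=False)
    manifest = {
        "package": "exacertrend",
        "version": __version__,
        "config": cfg.to_dict(),
        "config_sha256": cfg.digest(),
        "seed": cfg.seed,
        "n_cohort": len(cohort),
        "n_analysis_cohort": len(analysis_cohort),
        "n_episodes": int(len(episodes)),
        "versions": {"pandas": pd.__version__},
    }
    (cfg.outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    outputs["manifest"] = manifest
    return outputs
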