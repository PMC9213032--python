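"""Clinical codelists used for cohort identification and episode ascertainment.

A codelist is a named set of clinical codes with a *role* describing how the
pipeline uses it:

``asthma_diagnosis``
    Diagnosis codes defining the asthma cohort, and required on the day of a
    hospital admission for the admission to count as asthma-related.
``ae_attendance``
    Accident & Emergency attendance codes; each recorded code is itself an
    exacerbation trigger (hospital setting).
``hospital_admission``
    Hospital-admission codes; a trigger only when an asthma_diagnosis code is
    recorded for the same patient on the same day.
``respiratory_review``
    Respiratory-review consultation codes; evidence that an oral
    corticosteroid (OCS) prescription treated an exacerbation.
``ocs``
    Identifiers (drug-class strings) of rescue oral corticosteroids in the
    prescription table.

The loader accepts any codelist file; no particular coding system is assumed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .exceptions import ConfigurationError

ROLES = (
    "asthma_diagnosis",
    "ae_attendance",
    "hospital_admission",
    "respiratory_review",
    "ocs",
)

# Historic alias: some codelist files label A&E attendance codes this way.
_ROLE_ALIASES = {"hospital_attendance": "ae_attendance"}


@dataclass(frozen=True)
class Codelist:
    """A named, non-empty set of clinical codes with a pipeline role."""

    name: str
    codes: frozenset[str]
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigurationError(
                f"codelist {self.name!r}: unknown role {self.role!r}; "
                f"expected one of {ROLES}"
            )
        if not self.codes:
            raise ConfigurationError(f"codelist {self.name!r} is empty")

    def __contains__(self, code: str) -> bool:
        return code in self.codes


@dataclass
class CodelistSet:
    """The full set of codelists the pipeline needs, keyed by role."""

    by_role: dict[str, Codelist] = field(default_factory=dict)

    def __getitem__(self, role: str) -> Codelist:
        role = _ROLE_ALIASES.get(role, role)
        try:
            return self.by_role[role]
        except KeyError:
            raise ConfigurationError(f"no codelist with role {role!r} loaded") from None

    def require(self, *roles: str) -> None:
        for role in roles:
            self[role]


def load_codelists(path: str | Path) -> CodelistSet:
    """Load codelists from a CSV file (columns: code, description, role)
    or a directory of such files. Codes sharing a role are merged."""
    path = Path(path)
    files = sorted(path.glob("*.csv")) if path.is_dir() else [path]
    if not files:
        raise ConfigurationError(f"no codelist CSV files found under {path}")
    codes_by_role: dict[str, set[str]] = {}
    for f in files:
        df = pd.read_csv(f, dtype=str)
        missing = {"code", "role"} - set(df.columns)
        if missing:
            raise ConfigurationError(f"codelist file {f} lacks columns {sorted(missing)}")
        for role, grp in df.groupby("role"):
            role = _ROLE_ALIASES.get(str(role), str(role))
            codes_by_role.setdefault(role, set()).update(grp["code"].astype(str))
    return CodelistSet(
        {role: Codelist(name=role, codes=frozenset(codes), role=role)
         for role, codes in codes_by_role.items()}
    )


def bundled_codelists() -> CodelistSet:
    """The synthetic codelists shipped with the package (used by the
    simulator and the examples; real analyses supply their own files)."""
    with resources.as_file(
        resources.files("exacertrend.data") / "codelists" / "synthetic_codelists.csv"
    ) as p:
        return load_codelists(p)
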