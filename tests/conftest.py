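"""Shared fixtures: small synthetic cohorts and codelists."""
from __future__ import annotations

import pytest

from exacertrend.codelists import bundled_codelists
from exacertrend.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def codelists():
    return bundled_codelists()


@pytest.fixture(scope="session")
def small_cfg():
    """A 300-patient cohort over the full study follow-up."""
    return SimConfig(n_patients=300, seed=11)


@pytest.fixture(scope="session")
def small_tables(small_cfg):
    return simulate(small_cfg)


@pytest.fixture(scope="session")
def midsize_tables():
    """A 20,000-patient cohort for distributional checks."""
    return simulate(SimConfig(n_patients=20_000, seed=5), patient_week_truth=False)
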