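"""Shared fixtures: hand-built cohorts and small simulated worlds."""

from __future__ import annotations

import pandas as pd
import pytest

from ttecr.cohort import CANONICAL_COLUMNS, Cohort
from ttecr.emulate import ProtocolConfig

_DEFAULTS = {
    "age": 60.0, "sex": 1, "spo2": 90.0, "resp_rate": 20.0,
    "creatinine": 1.0, "admission_month": "mar", "treatment_day": None,
}


def make_cohort(rows: list[dict]) -> Cohort:
    """Build a cohort from partial row dicts, filling covariate defaults."""
    full = []
    for i, row in enumerate(rows):
        rec = {"patient_id": i + 1, **_DEFAULTS, **row}
        full.append(rec)
    return Cohort(pd.DataFrame(full, columns=list(CANONICAL_COLUMNS)))


@pytest.fixture
def protocol() -> ProtocolConfig:
    return ProtocolConfig(grace_period_days=2, max_followup_days=60)


@pytest.fixture
def fig1_cohort() -> Cohort:
    """Ten patients spanning every protocol pattern.

    IDs 1-4 start treatment inside the two-day grace period, IDs 5-6 start
    after it, IDs 7-10 are never treated; odd IDs die, even IDs are
    discharged alive, all after the grace period.
    """
    rows = [
        {"patient_id": 1, "treatment_day": 1, "event_day": 9, "event_type": "death"},
        {"patient_id": 2, "treatment_day": 2, "event_day": 10, "event_type": "discharge"},
        {"patient_id": 3, "treatment_day": 1, "event_day": 5, "event_type": "death"},
        {"patient_id": 4, "treatment_day": 2, "event_day": 12, "event_type": "discharge"},
        {"patient_id": 5, "treatment_day": 4, "event_day": 8, "event_type": "death"},
        {"patient_id": 6, "treatment_day": 5, "event_day": 11, "event_type": "discharge"},
        {"patient_id": 7, "treatment_day": None, "event_day": 10, "event_type": "death"},
        {"patient_id": 8, "treatment_day": None, "event_day": 9, "event_type": "discharge"},
        {"patient_id": 9, "treatment_day": None, "event_day": 7, "event_type": "death"},
        {"patient_id": 10, "treatment_day": None, "event_day": 6, "event_type": "discharge"},
    ]
    cohort = make_cohort([{k: v for k, v in r.items()} for r in rows])
    return cohort


@pytest.fixture(scope="session")
def small_sim_cohort():
    from ttecr.simulate import simulate_cohort, unconfounded_config

    return simulate_cohort(unconfounded_config(n=400, seed=3))
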