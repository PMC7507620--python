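"""Shared fixtures: record builders and small deterministic cohorts."""

from __future__ import annotations

from datetime import date, timedelta

import pytest

from etsm import ClassifierSpec, GeneratorConfig, generate_cohort
from etsm.cohort import PatientRecord

BASE = date(2024, 3, 1)


def make_record(
    patient_id: str,
    stay_days: int,
    creatinine: list[tuple[int, float]] | None = None,
    measurements: dict[str, list[tuple[int, float]]] | None = None,
    daily_drugs: dict[int, set[str]] | None = None,
) -> PatientRecord:
    rec = PatientRecord(
        patient_id=patient_id,
        admission_date=BASE,
        discharge_date=BASE + timedelta(days=stay_days),
        measurements=measurements or {},
        daily_drugs={d: frozenset(s) for d, s in (daily_drugs or {}).items()},
        creatinine=creatinine or [],
    )
    rec.validate()
    return rec


@pytest.fixture
def five_patient_cohort():
    """Five stays exercising every exclusion rule at a 24 h lead.

    p1, p4, p5 are retained (p4 develops AKI on day 3); p2 carries no
    measurement or medication data at all; p3 is a 12-hour stay.
    """
    flat = [(0, 1.0), (1, 1.1), (2, 1.05), (3, 1.1), (4, 1.0), (5, 1.1)]
    records = [
        make_record(
            "p1", 5, creatinine=flat[:6],
            measurements={"hr": [(0, 80.0), (3, 95.0)]},
            daily_drugs={0: {"a"}, 1: {"a", "b"}},
        ),
        make_record("p2", 5),
        make_record(
            "p3", 0, creatinine=[(0, 1.0)], measurements={"hr": [(0, 70.0)]},
        ),
        make_record(
            "p4", 6,
            creatinine=[(0, 1.0), (1, 1.1), (2, 1.1), (3, 1.5), (4, 1.6), (5, 1.6), (6, 1.6)],
            measurements={"hr": [(0, 88.0), (2, 100.0)]},
            daily_drugs={0: {"a", "c"}, 1: {"a", "c"}, 2: {"b"}},
        ),
        make_record(
            "p5", 7, creatinine=flat + [(6, 1.0), (7, 1.05)],
            measurements={"hr": [(0, 75.0), (6, 77.0)]},
            daily_drugs={2: {"b"}},
        ),
    ]
    return records


#: classifier settings that learn on cohorts of a few hundred samples (the
#: headline hyperparameters target cohorts in the thousands)
SMALL_CLASSIFIER = ClassifierSpec(n_estimators=40, max_depth=3, min_child_weight=1.0)


@pytest.fixture(scope="session")
def small_cohort():
    """A 160-patient synthetic cohort shared across protocol tests."""
    cfg = GeneratorConfig(n_patients=160, seed=42)
    return generate_cohort(cfg)
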