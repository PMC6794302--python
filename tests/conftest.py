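"""Shared builders for the test suite: tiny hand-made registries and timelines."""

from __future__ import annotations

import pytest

from trajmine.records import AdmissionRecord, PatientTimeline


def make_timeline(pid: str, days: dict[str, int], death_day: int | None = None,
                  ages: dict[str, float] | None = None) -> PatientTimeline:
    return PatientTimeline(
        patient_id=pid,
        first_dx_day=dict(days),
        death_day=death_day,
        ages=ages or {c: 60.0 for c in days},
    )


def make_record(pid="p1", edition="2010", day=0, codes=("295",), died=False, age=60.0):
    return AdmissionRecord(
        patient_id=pid,
        edition_id=edition,
        admission_day=day,
        diagnosis_codes=tuple(codes),
        died_in_hospital=died,
        age_years=age,
    )


@pytest.fixture
def toy_records():
    """Three patients, two editions; patient pB died in the old edition."""
    return [
        make_record("pA", "2009", 10, ("295.3", "728.88")),
        make_record("pB", "2009", 20, ("410",), died=True),
        make_record("pC", "2010", 5, ("428",)),
        make_record("pC", "2010", 100, ("428",)),
        make_record("pC", "2010", 300, ("486",)),
    ]
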