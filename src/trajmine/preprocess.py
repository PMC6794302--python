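"""Raw multi-edition admissions → deduplicated patient timelines.

The source registries release one edition per year; each edition carries a
patient's full longitudinal history under edition-local identifiers that
cannot be linked across editions. Keeping every edition would count
surviving patients several times, so the merge rule keeps the latest
edition in full and, from earlier editions, only patients who died in
hospital there (a deceased patient cannot reappear later).

Downstream of the merge the pipeline uses the principal (first charted)
diagnosis of each admission, truncates codes to the three-digit chapter
level, drops admissions whose principal diagnosis is not a disease
(pregnancy/childbirth, injury/poisoning, external causes, administrative
codes), and collapses readmissions for the same code to the first
occurrence.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import CodingError, ConfigurationError, RecordError
from .records import AdmissionRecord, PatientTimeline

__all__ = [
    "MergePolicy",
    "merge_editions",
    "principal_diagnosis",
    "round_to_three_digit",
    "filter_nondisease",
    "build_timelines",
    "prepare_timelines",
]

logger = logging.getLogger(__name__)

_NUMERIC = re.compile(r"^(\d{3})(?:\.\d{1,2})?$")
_VCODE = re.compile(r"^V(\d{2})(?:\.\d{1,2})?$")
_ECODE = re.compile(r"^E(\d{3})(?:\.\d)?$")


@dataclass(frozen=True)
class MergePolicy:
    """How to merge multi-edition registries without double counting.

    ``latest_edition`` is retained in full; other editions contribute only
    patients with an in-hospital death there (when
    ``backfill_requires_death``, the default and the only sound choice for
    registries without cross-edition linkage).
    """

    latest_edition: str
    backfill_requires_death: bool = True


def merge_editions(
    records: Sequence[AdmissionRecord], policy: MergePolicy
) -> list[AdmissionRecord]:
    """Merge editions per ``policy``; record order is preserved.

    Raises :class:`ConfigurationError` if ``policy.latest_edition`` does
    not occur in the data.
    """
    editions = {r.edition_id for r in records}
    if records and policy.latest_edition not in editions:
        raise ConfigurationError(
            f"latest edition {policy.latest_edition!r} not present in data "
            f"(editions found: {sorted(editions)})"
        )
    if editions <= {policy.latest_edition}:
        return list(records)

    deceased: set[tuple[str, str]] = {
        (r.edition_id, r.patient_id) for r in records if r.died_in_hospital
    }
    out: list[AdmissionRecord] = []
    for r in records:
        if r.edition_id == policy.latest_edition:
            out.append(r)
        elif not policy.backfill_requires_death or (r.edition_id, r.patient_id) in deceased:
            out.append(r)
    return out


def principal_diagnosis(record: AdmissionRecord) -> str:
    """The first charted diagnosis of an admission."""
    if not record.diagnosis_codes:
        raise RecordError(f"admission of {record.patient_id!r} has no diagnoses")
    return record.diagnosis_codes[0]


def round_to_three_digit(code: str) -> str:
    """Truncate an ICD-9-CM code to its three-digit chapter level.

    Numeric codes keep the first three digits (``728.88`` → ``728``);
    V codes keep ``V`` plus two digits (``V58.11`` → ``V58``); E codes keep
    ``E`` plus three digits (``E880.0`` → ``E880``). Truncation avoids
    splitting one disease across sub-classification codes.
    """
    code = code.strip()
    m = _NUMERIC.match(code)
    if m:
        return m.group(1)
    m = _VCODE.match(code)
    if m:
        return "V" + m.group(1)
    m = _ECODE.match(code)
    if m:
        return "E" + m.group(1)
    raise CodingError(f"not a valid ICD-9-CM code: {code!r}")


#: Three-digit principal-diagnosis ranges excluded as non-disease.
#: Category name → predicate on the rounded code.
_EXCLUSIONS = {
    "pregnancy_childbirth": lambda c: c.isdigit() and 630 <= int(c) <= 679,
    "injury_poisoning": lambda c: c.isdigit() and 800 <= int(c) <= 999,
    "external_causes": lambda c: c.startswith("E"),
    "administrative": lambda c: c.startswith("V"),
}


def nondisease_category(code: str) -> str | None:
    """Exclusion category of a rounded three-digit code, or None if a disease."""
    for name, pred in _EXCLUSIONS.items():
        if pred(code):
            return name
    return None


def filter_nondisease(
    records: Sequence[AdmissionRecord],
) -> tuple[list[AdmissionRecord], dict[str, int]]:
    """Drop admissions whose principal diagnosis is not a disease.

    The principal diagnosis must already be three-digit rounded. Returns
    the retained records and a per-category count of dropped admissions
    (the filtering report).
    """
    report = {name: 0 for name in _EXCLUSIONS}
    kept: list[AdmissionRecord] = []
    for r in records:
        cat = nondisease_category(r.principal_diagnosis)
        if cat is None:
            kept.append(r)
        else:
            report[cat] += 1
    return kept, report


def build_timelines(records: Iterable[AdmissionRecord]) -> list[PatientTimeline]:
    """Collapse admissions to per-patient first-diagnosis timelines.

    Records must already be merged, rounded and filtered. Per patient,
    the earliest admission day per principal code is kept; the death day is
    the earliest death-flagged admission day (death is terminal — later
    records for a dead patient are ignored with a warning).
    """
    by_patient: dict[str, list[AdmissionRecord]] = defaultdict(list)
    editions_seen: dict[str, set[str]] = defaultdict(set)
    for r in records:
        by_patient[r.patient_id].append(r)
        editions_seen[r.patient_id].add(r.edition_id)

    multi = [p for p, eds in editions_seen.items() if len(eds) > 1]
    if multi:
        logger.warning(
            "%d patient ids appear in multiple editions after merging; "
            "collapsing by patient_id (first few: %s)",
            len(multi),
            multi[:5],
        )

    timelines: list[PatientTimeline] = []
    for pid, recs in by_patient.items():
        recs = sorted(recs, key=lambda r: r.admission_day)
        death_day: int | None = None
        for r in recs:
            if r.died_in_hospital:
                death_day = r.admission_day
                break
        tl = PatientTimeline(patient_id=pid, death_day=death_day)
        dropped_after_death = 0
        for r in recs:
            if death_day is not None and r.admission_day > death_day:
                dropped_after_death += 1
                continue
            code = r.principal_diagnosis
            if code not in tl.first_dx_day:
                tl.first_dx_day[code] = r.admission_day
                tl.ages[code] = r.age_years
        if dropped_after_death:
            logger.warning(
                "patient %r has %d admissions after the death-flagged one; dropped",
                pid,
                dropped_after_death,
            )
        timelines.append(tl)
    return timelines


def prepare_timelines(
    records: Sequence[AdmissionRecord],
    policy: MergePolicy | None = None,
) -> tuple[list[PatientTimeline], dict[str, int]]:
    """Full preprocessing chain: merge → round → filter → timelines.

    Convenience wrapper used by the pipeline; returns the timelines and
    the non-disease filtering report.
    """
    if policy is not None:
        records = merge_editions(records, policy)
    rounded = [
        AdmissionRecord(
            patient_id=r.patient_id,
            edition_id=r.edition_id,
            admission_day=r.admission_day,
            diagnosis_codes=tuple(round_to_three_digit(c) for c in r.diagnosis_codes),
            died_in_hospital=r.died_in_hospital,
            age_years=r.age_years,
        )
        for r in records
    ]
    kept, report = filter_nondisease(rounded)
    return build_timelines(kept), report
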