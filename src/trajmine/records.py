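"""Domain types for inpatient admission data and the delimited-text interchange format.

The interchange format is a CSV/TSV with a header row and one row per
hospital admission::

    patient_id,edition_id,admission_day,diagnosis_codes,died_in_hospital,age_years
    p0001,2010,512,295.3|728.88,0,54.2

``diagnosis_codes`` is a sub-delimited (default ``|``) ordered list of
ICD-9-CM codes; the first entry is the principal diagnosis.
``admission_day`` is an integer day-offset from an arbitrary fixed epoch:
the source registries are deidentified, only intervals between admissions
carry meaning.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import FormatError, RecordError, RowError

__all__ = [
    "AdmissionRecord",
    "PatientTimeline",
    "read_admissions",
    "write_admissions",
]

#: Column order of the interchange format.
COLUMNS = (
    "patient_id",
    "edition_id",
    "admission_day",
    "diagnosis_codes",
    "died_in_hospital",
    "age_years",
)


@dataclass(frozen=True)
class AdmissionRecord:
    """One hospitalization.

    Attributes
    ----------
    patient_id:
        Opaque patient identifier; unique within an edition only.
    edition_id:
        Registry release label (e.g. ``"2010"``); patient identifiers
        cannot be linked across editions.
    admission_day:
        Integer day-offset from a fixed (unknown) epoch.
    diagnosis_codes:
        Ordered ICD-9-CM codes; the first is the principal diagnosis.
    died_in_hospital:
        True if the patient died during this admission.
    age_years:
        Patient age at admission, in years.
    """

    patient_id: str
    edition_id: str
    admission_day: int
    diagnosis_codes: tuple[str, ...]
    died_in_hospital: bool
    age_years: float

    def __post_init__(self) -> None:
        if len(self.diagnosis_codes) == 0:
            raise RecordError(
                f"admission of patient {self.patient_id!r} has no diagnosis codes"
            )
        if self.age_years < 0:
            raise RecordError(
                f"admission of patient {self.patient_id!r} has negative age"
            )

    @property
    def principal_diagnosis(self) -> str:
        """The first charted diagnosis — the main reason for the admission."""
        return self.diagnosis_codes[0]


@dataclass
class PatientTimeline:
    """Per-patient first-diagnosis timeline.

    Readmissions for the same three-digit code are collapsed: only the
    earliest admission day per code is kept.
    """

    patient_id: str
    first_dx_day: dict[str, int] = field(default_factory=dict)
    death_day: Optional[int] = None
    ages: dict[str, float] = field(default_factory=dict)

    @property
    def codes(self) -> set[str]:
        return set(self.first_dx_day)


def read_admissions(
    path: str | Path,
    delimiter: str = ",",
    code_delimiter: str = "|",
) -> list[AdmissionRecord]:
    """Read admission records from a delimited-text file.

    Parameters
    ----------
    path:
        File to read. Must have a header naming all of :data:`COLUMNS`.
    delimiter:
        Field delimiter ("," for CSV, "\\t" for TSV).
    code_delimiter:
        Sub-delimiter packing the ordered diagnosis codes into one field.

    Raises
    ------
    FormatError
        If a mandatory column is missing from the header.
    RowError
        If a row has an unparseable day, flag or age; the error names the
        1-based data row index.
    """
    path = Path(path)
    records: list[AdmissionRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for col in COLUMNS:
            if col not in header:
                raise FormatError(f"missing mandatory column {col!r} in {path}")
        for i, row in enumerate(reader, start=1):
            try:
                day = int(row["admission_day"])
                died = _parse_flag(row["died_in_hospital"])
                age = float(row["age_years"])
            except (TypeError, ValueError) as exc:
                raise RowError(i, str(exc)) from exc
            codes = tuple(
                c for c in (row["diagnosis_codes"] or "").split(code_delimiter) if c
            )
            if not codes:
                raise RowError(i, "empty diagnosis_codes field")
            records.append(
                AdmissionRecord(
                    patient_id=row["patient_id"],
                    edition_id=row["edition_id"],
                    admission_day=day,
                    diagnosis_codes=codes,
                    died_in_hospital=died,
                    age_years=age,
                )
            )
    return records


def write_admissions(
    records: Iterable[AdmissionRecord],
    path: str | Path,
    delimiter: str = ",",
    code_delimiter: str = "|",
) -> None:
    """Write admission records; inverse of :func:`read_admissions`.

    Rows are written in input order; reading the file back reproduces the
    records field-for-field.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.patient_id,
                    rec.edition_id,
                    rec.admission_day,
                    code_delimiter.join(rec.diagnosis_codes),
                    int(rec.died_in_hospital),
                    repr(rec.age_years),
                ]
            )


def _parse_flag(raw: str) -> bool:
    value = raw.strip().lower()
    if value in {"0", "false"}:
        return False
    if value in {"1", "true"}:
        return True
    raise ValueError(f"invalid death flag {raw!r}")
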