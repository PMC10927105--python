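"""Canonical record types and delimited-table I/O shared by every pipeline stage.

All tables are UTF-8 CSV with a header row.  Code sets (diagnosis, drug,
procedure) are serialized inside a single field as pipe-joined, sorted
strings; calendar dates serialize as ISO-8601 (no times, no locale).  Date
intervals throughout the package are half-open ``[start, end)``.

Five record types are defined:

* :class:`ClaimRecord` — one healthcare encounter line,
* :class:`StudySiteEnrollment` — one site's participation in one study
  (the target rows: enrolled count plus enrollment-months exposure),
* :class:`CohortDefinition` — code lists and windows defining the eligible
  patient population,
* :class:`PublicationRecord` — indication-filtered publication counts per
  physician,
* :class:`TrialParticipationRecord` — per-site trial-participation rows.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Any, Callable, Iterable, Sequence, Type, TypeVar

import pandas as pd
import yaml

__all__ = [
    "ClaimRecord",
    "StudySiteEnrollment",
    "CohortDefinition",
    "PublicationRecord",
    "TrialParticipationRecord",
    "TableSchemaError",
    "RowValidationError",
    "read_table",
    "write_table",
    "to_frame",
    "read_frame",
    "load_cohort",
    "save_cohort",
]

# Months-per-day conversion used wherever enrollment durations in months are
# compared against calendar-date spans (mean Gregorian month length).
DAYS_PER_MONTH = 30.436875


class TableSchemaError(ValueError):
    """The file header does not match the expected schema."""


class RowValidationError(ValueError):
    """A row violates a type invariant; carries the 1-based data row number."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


# ---------------------------------------------------------------------------
# field (de)serialization helpers


def _parse_date(s: str) -> dt.date:
    return dt.date.fromisoformat(s)


def _parse_opt_date(s: str) -> dt.date | None:
    return dt.date.fromisoformat(s) if s else None


def _render_date(d: dt.date) -> str:
    return d.isoformat()


def _render_opt_date(d: dt.date | None) -> str:
    return d.isoformat() if d is not None else ""


def _parse_codes(s: str) -> frozenset[str]:
    return frozenset(s.split("|")) if s else frozenset()


def _render_codes(codes: Iterable[str]) -> str:
    return "|".join(sorted(codes))


def _render_bool(b: bool) -> str:
    return "1" if b else "0"


def _parse_bool(s: str) -> bool:
    if s in ("1", "true", "True"):
        return True
    if s in ("0", "false", "False"):
        return False
    raise ValueError(f"not a boolean flag: {s!r}")


_CONVERTERS: dict[str, tuple[Callable[[str], Any], Callable[[Any], str]]] = {
    "str": (str, str),
    "int": (int, str),
    "float": (float, repr),
    "bool": (_parse_bool, _render_bool),
    "date": (_parse_date, _render_date),
    "opt_date": (_parse_opt_date, _render_opt_date),
    "codes": (_parse_codes, _render_codes),
}


# ---------------------------------------------------------------------------
# record types


@dataclass(frozen=True)
class ClaimRecord:
    """One healthcare encounter line (inpatient/outpatient/ED/institutional)."""

    patient_id: str
    hco_id: str
    physician_id: str
    specialty: str
    service_date: dt.date
    visit_id: str
    diagnosis_codes: frozenset[str]
    drug_codes: frozenset[str]
    procedure_codes: frozenset[str]
    patient_age: int

    _kinds = {
        "patient_id": "str",
        "hco_id": "str",
        "physician_id": "str",
        "specialty": "str",
        "service_date": "date",
        "visit_id": "str",
        "diagnosis_codes": "codes",
        "drug_codes": "codes",
        "procedure_codes": "codes",
        "patient_age": "int",
    }

    def validate(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if not self.hco_id:
            raise ValueError("hco_id must be non-empty")
        if self.patient_age < 0:
            raise ValueError(f"patient_age must be >= 0, got {self.patient_age}")


@dataclass(frozen=True)
class StudySiteEnrollment:
    """One site's participation in one study: the target y and exposure E.

    ``enrollment_months`` is the time between the site open date and the
    date of the last subject enrolled; when ``last_subject_date`` is present
    the two must agree within half a month.
    """

    study_id: str
    site_id: str
    site_open_date: dt.date
    first_subject_date: dt.date | None
    last_subject_date: dt.date | None
    enrollment_months: float
    patients_enrolled: int

    _kinds = {
        "study_id": "str",
        "site_id": "str",
        "site_open_date": "date",
        "first_subject_date": "opt_date",
        "last_subject_date": "opt_date",
        "enrollment_months": "float",
        "patients_enrolled": "int",
    }

    def validate(self) -> None:
        if not self.study_id or not self.site_id:
            raise ValueError("study_id and site_id must be non-empty")
        if self.enrollment_months <= 0:
            raise ValueError(
                f"enrollment_months must be > 0, got {self.enrollment_months}"
            )
        if self.patients_enrolled < 0:
            raise ValueError("patients_enrolled must be >= 0")
        if self.first_subject_date is not None and self.last_subject_date is not None:
            if self.first_subject_date > self.last_subject_date:
                raise ValueError("first_subject_date after last_subject_date")
        if self.last_subject_date is not None:
            span_months = (
                self.last_subject_date - self.site_open_date
            ).days / DAYS_PER_MONTH
            if abs(span_months - self.enrollment_months) > 0.5:
                raise ValueError(
                    "enrollment_months inconsistent with site_open_date.."
                    f"last_subject_date span ({span_months:.2f} vs "
                    f"{self.enrollment_months:.2f} months)"
                )


@dataclass(frozen=True)
class PublicationRecord:
    """Indication-filtered publication count of one physician at one HCO."""

    physician_id: str
    hco_id: str
    n_publications: int

    _kinds = {"physician_id": "str", "hco_id": "str", "n_publications": "int"}

    def validate(self) -> None:
        if self.n_publications < 0:
            raise ValueError("n_publications must be >= 0")


@dataclass(frozen=True)
class TrialParticipationRecord:
    """One trial a site participated in (sponsor-of-interest and ongoing flags)."""

    hco_id: str
    trial_id: str
    sponsor_flag: bool
    ongoing_flag: bool

    _kinds = {
        "hco_id": "str",
        "trial_id": "str",
        "sponsor_flag": "bool",
        "ongoing_flag": "bool",
    }

    def validate(self) -> None:
        if not self.trial_id:
            raise ValueError("trial_id must be non-empty")


@dataclass(frozen=True)
class CohortDefinition:
    """Code lists, age range and observation window approximating a trial's
    eligible patient population in claims data.

    The observation window is half-open: a claim qualifies when
    ``observation_start <= service_date < observation_end``.  Diagnosis codes
    define the "relevant claim"; drug/procedure codes define treatment status.
    """

    observation_start: dt.date
    observation_end: dt.date
    min_age: int
    max_age: int
    diagnosis_codes: frozenset[str]
    drug_codes: frozenset[str]
    procedure_codes: frozenset[str]
    specialist_types: frozenset[str]

    def validate(self) -> None:
        if self.observation_start >= self.observation_end:
            raise ValueError("observation window start must precede end")
        if self.min_age > self.max_age:
            raise ValueError("min_age must be <= max_age")
        if not self.diagnosis_codes:
            raise ValueError("cohort diagnosis_codes must be non-empty")


RecordT = TypeVar(
    "RecordT",
    ClaimRecord,
    StudySiteEnrollment,
    PublicationRecord,
    TrialParticipationRecord,
)

SCHEMAS: tuple[type, ...] = (
    ClaimRecord,
    StudySiteEnrollment,
    PublicationRecord,
    TrialParticipationRecord,
)


def _field_names(record_type: type) -> list[str]:
    return [f.name for f in dc_fields(record_type)]


# ---------------------------------------------------------------------------
# table I/O


def read_table(path: str | Path, record_type: Type[RecordT]) -> list[RecordT]:
    """Read a CSV table into validated records, preserving row order.

    Raises :class:`TableSchemaError` if a required column is missing and
    :class:`RowValidationError` (with the 1-based data row number) if a row
    cannot be parsed or violates a type invariant.
    """
    path = Path(path)
    names = _field_names(record_type)
    kinds = record_type._kinds
    records: list[RecordT] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [n for n in names if n not in header]
        if missing:
            raise TableSchemaError(
                f"{path.name}: missing required column(s) {', '.join(missing)}"
            )
        for i, row in enumerate(reader, start=1):
            values = {}
            for name in names:
                parse = _CONVERTERS[kinds[name]][0]
                try:
                    values[name] = parse(row[name])
                except (ValueError, TypeError) as exc:
                    raise RowValidationError(i, f"field {name}: {exc}") from exc
            record = record_type(**values)
            try:
                record.validate()
            except ValueError as exc:
                raise RowValidationError(i, str(exc)) from exc
            records.append(record)
    return records


def write_table(
    records: Sequence[Any], path: str | Path, record_type: type | None = None
) -> Path:
    """Write records as a UTF-8 CSV with header; inverse of :func:`read_table`.

    ``record_type`` is required when ``records`` is empty (to emit the header).
    """
    if record_type is None:
        if not records:
            raise ValueError("record_type required for an empty record sequence")
        record_type = type(records[0])
    names = _field_names(record_type)
    kinds = record_type._kinds
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(names)
        for rec in records:
            if not isinstance(rec, record_type):
                raise TypeError(
                    f"heterogeneous records: expected {record_type.__name__}, "
                    f"got {type(rec).__name__}"
                )
            writer.writerow(
                [_CONVERTERS[kinds[n]][1](getattr(rec, n)) for n in names]
            )
    return path


def to_frame(records: Sequence[Any], record_type: type | None = None) -> pd.DataFrame:
    """Convert records to a DataFrame (dates become pandas Timestamps; code
    sets stay frozensets in object columns)."""
    if record_type is None:
        if not records:
            raise ValueError("record_type required for an empty record sequence")
        record_type = type(records[0])
    names = _field_names(record_type)
    kinds = record_type._kinds
    frame = pd.DataFrame([{n: getattr(r, n) for n in names} for r in records],
                         columns=names)
    for n in names:
        if kinds[n] in ("date", "opt_date"):
            frame[n] = pd.to_datetime(frame[n])
    return frame


def read_frame(path: str | Path, record_type: Type[RecordT]) -> pd.DataFrame:
    """Read and validate a table, returning it as a DataFrame."""
    return to_frame(read_table(path, record_type), record_type)


# ---------------------------------------------------------------------------
# cohort definition (YAML/JSON-compatible mapping)


def load_cohort(path: str | Path) -> CohortDefinition:
    with Path(path).open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    cohort = CohortDefinition(
        observation_start=_as_date(raw["observation_start"]),
        observation_end=_as_date(raw["observation_end"]),
        min_age=int(raw["min_age"]),
        max_age=int(raw["max_age"]),
        diagnosis_codes=frozenset(raw["diagnosis_codes"]),
        drug_codes=frozenset(raw.get("drug_codes", [])),
        procedure_codes=frozenset(raw.get("procedure_codes", [])),
        specialist_types=frozenset(raw.get("specialist_types", [])),
    )
    cohort.validate()
    return cohort


def save_cohort(cohort: CohortDefinition, path: str | Path) -> Path:
    payload = {
        "observation_start": cohort.observation_start.isoformat(),
        "observation_end": cohort.observation_end.isoformat(),
        "min_age": cohort.min_age,
        "max_age": cohort.max_age,
        "diagnosis_codes": sorted(cohort.diagnosis_codes),
        "drug_codes": sorted(cohort.drug_codes),
        "procedure_codes": sorted(cohort.procedure_codes),
        "specialist_types": sorted(cohort.specialist_types),
    }
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
    return path


def _as_date(value: Any) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))
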