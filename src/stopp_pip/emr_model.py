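"""Coded-EMR data model: patients, encounters, medications, problem list.

The four tables mirror what a community primary-care EMR exposes to a
query engine: demographics with an EMR-maintained ``active`` flag,
encounter dates, prescriptions with optional ATC codes (an empty code
means the prescription was written as free text and is invisible to any
coded query), and a problem list whose entries always carry a diagnostic
code.

Conventions used throughout the package:

* Dates are ISO-8601 strings on disk and ``datetime.date`` in memory.
* All intervals are closed on both ends and computed in whole days.
* "Past N months" means ``ref_date - floor(N * 365.25 / 12)`` days.
* Missing values are empty fields in CSV and ``null`` in JSON-lines.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "ATC_PATTERN",
    "PatientRecord",
    "EncounterRecord",
    "MedicationRecord",
    "ProblemRecord",
    "ClinicDataset",
    "RowIssue",
    "SchemaError",
    "ReferentialError",
    "age_at",
    "past_months",
    "med_active_in",
    "med_current",
    "parse_date",
    "read_clinic_dataset",
    "write_clinic_dataset",
]

#: Lexical shape of a full ATC code: letter, 2 digits, then optionally
#: letter, letter, 2 digits (levels 1-5).  Prefix matching elsewhere
#: accepts truncations of this shape.
ATC_PATTERN = re.compile(r"^[A-Z]\d{2}([A-Z]([A-Z](\d{2})?)?)?$")

DAYS_PER_MONTH = 365.25 / 12.0

GENDERS = frozenset({"M", "F", "other"})
CODE_SYSTEMS = frozenset({"ICD9", "ICD10"})
ARMS = frozenset({"control", "intervention"})

#: A clinic is "small" below this many physicians, "large" otherwise.
SMALL_CLINIC_MAX_PHYSICIANS = 4


class SchemaError(ValueError):
    """A table file is missing a required column or is malformed."""


class ReferentialError(ValueError):
    """A child table row references a patient_id that does not exist."""


def parse_date(s: Optional[str]) -> Optional[date]:
    """Parse an ISO-8601 date string; ``None``/empty/garbage gives ``None``."""
    if not s:
        return None
    try:
        return date.fromisoformat(str(s).strip())
    except ValueError:
        return None


def past_months(ref_date: date, n_months: int) -> date:
    """Start of the closed lookback window "past ``n_months`` months"."""
    return ref_date - timedelta(days=int(n_months * DAYS_PER_MONTH))


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    clinic_id: str
    #: raw value as stored by the EMR; kept so that an unparsable or
    #: implausible date of birth remains observable to the probes
    #: instead of being silently rejected at load time.
    birth_date_raw: str = ""
    gender: Optional[str] = None  # "M" | "F" | "other" | None
    active_flag: bool = True

    @property
    def birth_date(self) -> Optional[date]:
        return parse_date(self.birth_date_raw)

    def has_dob(self) -> bool:
        return bool(self.birth_date_raw.strip())

    def dob_invalid(self, ref_date: date) -> bool:
        """Present but unusable: unparsable, in the future, or age > 120."""
        if not self.has_dob():
            return False
        d = self.birth_date
        if d is None:
            return True
        if d > ref_date:
            return True
        a = _age(d, ref_date)
        return a is not None and a > 120


@dataclass(frozen=True)
class EncounterRecord:
    patient_id: str
    encounter_date: date


@dataclass(frozen=True)
class MedicationRecord:
    patient_id: str
    drug_code: Optional[str]  # None => free-text / custom prescription
    drug_name: str
    start_date: date
    end_date: Optional[date]  # None => open-ended

    @property
    def coded(self) -> bool:
        return self.drug_code is not None


@dataclass(frozen=True)
class ProblemRecord:
    patient_id: str
    problem_code: str  # required: the EMR will not store an uncoded problem
    code_system: str  # "ICD9" | "ICD10"
    documented_date: date


@dataclass
class ClinicDataset:
    clinic_id: str
    patients: list[PatientRecord] = field(default_factory=list)
    encounters: list[EncounterRecord] = field(default_factory=list)
    medications: list[MedicationRecord] = field(default_factory=list)
    problems: list[ProblemRecord] = field(default_factory=list)
    arm: str = "control"  # "control" | "intervention"
    physician_count: int = 1

    @property
    def size_stratum(self) -> str:
        return "small" if self.physician_count < SMALL_CLINIC_MAX_PHYSICIANS else "large"

    def patient_index(self) -> dict[str, PatientRecord]:
        return {p.patient_id: p for p in self.patients}

    def validate(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dups = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
            raise ReferentialError(f"duplicate patient_id within clinic: {dups}")
        known = set(ids)
        bad: list[str] = []
        for table in (self.encounters, self.medications, self.problems):
            for r in table:
                if r.patient_id not in known:
                    bad.append(r.patient_id)
        if bad:
            raise ReferentialError(
                "unresolvable patient_id foreign keys: " + ", ".join(sorted(set(bad)))
            )
        if self.arm not in ARMS:
            raise SchemaError(f"unknown arm {self.arm!r}")


def _age(birth: date, ref: date) -> Optional[int]:
    if birth is None:
        return None
    years = ref.year - birth.year - ((ref.month, ref.day) < (birth.month, birth.day))
    return years


def age_at(p: PatientRecord, ref_date: date) -> Optional[int]:
    """Whole completed years at ``ref_date``; ``None`` when DOB is missing,
    unparsable, or in the future (an age cannot be negative)."""
    b = p.birth_date
    if b is None or b > ref_date:
        return None
    return _age(b, ref_date)


def med_active_in(m: MedicationRecord, window_start: date, window_end: date) -> bool:
    """Interval-overlap convention: active at any point of the closed window."""
    if m.start_date > window_end:
        return False
    return m.end_date is None or m.end_date >= window_start


def med_current(m: MedicationRecord, ref_date: date) -> bool:
    """Current = active on ``ref_date`` itself."""
    return med_active_in(m, ref_date, ref_date)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

TABLE_COLUMNS = {
    "patients": ["patient_id", "clinic_id", "birth_date", "gender", "active_flag"],
    "encounters": ["patient_id", "encounter_date"],
    "medications": ["patient_id", "drug_code", "drug_name", "start_date", "end_date"],
    "problems": ["patient_id", "problem_code", "code_system", "documented_date"],
}


@dataclass(frozen=True)
class RowIssue:
    table: str
    row: int  # 0-based data-row index
    message: str


def _read_rows(path: Path, table: str) -> list[dict[str, str]]:
    path = Path(path)
    cols = TABLE_COLUMNS[table]
    rows: list[dict[str, str]] = []
    if path.suffix == ".jsonl":
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                obj = json.loads(line)
                missing = [c for c in cols if c not in obj]
                if missing:
                    raise SchemaError(f"{path}: missing fields {missing}")
                rows.append({c: ("" if obj[c] is None else str(obj[c])) for c in cols})
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            missing = [c for c in cols if c not in header]
            if missing:
                raise SchemaError(f"{path}: missing columns {missing}")
            for obj in reader:
                rows.append({c: (obj[c] or "") for c in cols})
    return rows


def read_clinic_dataset(
    paths: dict[str, str | Path],
    clinic_id: str,
    arm: str = "control",
    physician_count: int = 1,
) -> tuple[ClinicDataset, list[RowIssue]]:
    """Load and validate the four tables of one clinic.

    ``paths`` maps table name (``patients``, ``encounters``,
    ``medications``, ``problems``) to a ``.csv`` or ``.jsonl`` file.
    Rows violating record-level invariants (bad dates, malformed ATC
    codes, wrong enumeration values) are rejected and reported in the
    returned :class:`RowIssue` list rather than silently dropped.  An
    unparsable date of *birth* is the one deliberate exception: it is a
    data-quality phenomenon the probe suite must be able to see, so the
    patient row is kept with the raw value.

    Raises :class:`SchemaError` for missing columns and
    :class:`ReferentialError` for unresolvable patient ids.
    """
    issues: list[RowIssue] = []

    patients: list[PatientRecord] = []
    for i, r in enumerate(_read_rows(Path(paths["patients"]), "patients")):
        if not r["patient_id"]:
            issues.append(RowIssue("patients", i, "empty patient_id"))
            continue
        gender = r["gender"] or None
        if gender is not None and gender not in GENDERS:
            issues.append(RowIssue("patients", i, f"unknown gender {gender!r}"))
            continue
        patients.append(
            PatientRecord(
                patient_id=r["patient_id"],
                clinic_id=r["clinic_id"] or clinic_id,
                birth_date_raw=r["birth_date"],
                gender=gender,
                active_flag=r["active_flag"].strip().lower() in ("true", "1", "yes"),
            )
        )

    encounters: list[EncounterRecord] = []
    for i, r in enumerate(_read_rows(Path(paths["encounters"]), "encounters")):
        d = parse_date(r["encounter_date"])
        if d is None:
            issues.append(RowIssue("encounters", i, f"bad encounter_date {r['encounter_date']!r}"))
            continue
        encounters.append(EncounterRecord(r["patient_id"], d))

    medications: list[MedicationRecord] = []
    for i, r in enumerate(_read_rows(Path(paths["medications"]), "medications")):
        start = parse_date(r["start_date"])
        if start is None:
            issues.append(RowIssue("medications", i, f"bad start_date {r['start_date']!r}"))
            continue
        end = parse_date(r["end_date"]) if r["end_date"] else None
        if r["end_date"] and end is None:
            issues.append(RowIssue("medications", i, f"bad end_date {r['end_date']!r}"))
            continue
        if end is not None and start > end:
            issues.append(RowIssue("medications", i, "start_date after end_date"))
            continue
        code = r["drug_code"].strip() or None
        if code is not None and not ATC_PATTERN.match(code):
            issues.append(RowIssue("medications", i, f"drug_code {code!r} not ATC-shaped"))
            continue
        medications.append(MedicationRecord(r["patient_id"], code, r["drug_name"], start, end))

    problems: list[ProblemRecord] = []
    for i, r in enumerate(_read_rows(Path(paths["problems"]), "problems")):
        if not r["problem_code"].strip():
            issues.append(RowIssue("problems", i, "empty problem_code"))
            continue
        if r["code_system"] not in CODE_SYSTEMS:
            issues.append(RowIssue("problems", i, f"unknown code_system {r['code_system']!r}"))
            continue
        d = parse_date(r["documented_date"])
        if d is None:
            issues.append(RowIssue("problems", i, f"bad documented_date {r['documented_date']!r}"))
            continue
        problems.append(ProblemRecord(r["patient_id"], r["problem_code"].strip(), r["code_system"], d))

    ds = ClinicDataset(
        clinic_id=clinic_id,
        patients=patients,
        encounters=encounters,
        medications=medications,
        problems=problems,
        arm=arm,
        physician_count=physician_count,
    )
    ds.validate()
    return ds, issues


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, date):
        return v.isoformat()
    return str(v)


def _patient_rows(ds: ClinicDataset) -> Iterable[list]:
    for p in ds.patients:
        yield [p.patient_id, p.clinic_id, p.birth_date_raw, p.gender, p.active_flag]


def _encounter_rows(ds: ClinicDataset) -> Iterable[list]:
    for e in ds.encounters:
        yield [e.patient_id, e.encounter_date]


def _medication_rows(ds: ClinicDataset) -> Iterable[list]:
    for m in ds.medications:
        yield [m.patient_id, m.drug_code, m.drug_name, m.start_date, m.end_date]


def _problem_rows(ds: ClinicDataset) -> Iterable[list]:
    for p in ds.problems:
        yield [p.patient_id, p.problem_code, p.code_system, p.documented_date]


_ROW_FNS = {
    "patients": _patient_rows,
    "encounters": _encounter_rows,
    "medications": _medication_rows,
    "problems": _problem_rows,
}


def write_clinic_dataset(ds: ClinicDataset, paths: dict[str, str | Path]) -> None:
    """Write the four tables; CSV or JSON-lines chosen by file suffix.

    Round-trip identity: :func:`read_clinic_dataset` on the written
    files reproduces the dataset field for field, including the
    distinction between a missing value and an empty string.
    """
    for table, cols in TABLE_COLUMNS.items():
        path = Path(paths[table])
        path.parent.mkdir(parents=True, exist_ok=True)
        rows = list(_ROW_FNS[table](ds))
        if path.suffix == ".jsonl":
            with open(path, "w") as fh:
                for row in rows:
                    obj = {
                        c: (
                            None
                            if v is None or v == ""
                            else (v if isinstance(v, bool) else _fmt(v))
                        )
                        for c, v in zip(cols, row)
                    }
                    fh.write(json.dumps(obj) + "\n")
        else:
            with open(path, "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(cols)
                for row in rows:
                    w.writerow([_fmt(v) for v in row])


def table_paths(directory: str | Path, fmt: str = "csv") -> dict[str, Path]:
    """Conventional per-table file names inside one clinic directory."""
    d = Path(directory)
    return {t: d / f"{t}.{fmt}" for t in TABLE_COLUMNS}
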