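"""Reading and writing corpora, labels, metadata and predictions, plus the
patient eligibility filter.

Documents travel as JSONL (canonical: free text with embedded newlines is
safe) or CSV with identical column names. All files are UTF-8 with a header
row; dates are ISO-8601 strings and never used computationally.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class CorpusError(ValueError):
    """Malformed corpus input: missing columns, duplicate ids, bad encoding."""


@dataclass(frozen=True)
class ClinicalDocument:
    """One free-text clinical note tied to a patient."""

    doc_id: str
    patient_id: str
    text: str
    created: str | None = None


@dataclass(frozen=True)
class PatientMetadata:
    """Eligibility attributes for one patient.

    ``None`` means the attribute is missing from the source record; the
    eligibility filter treats missing conservatively, as failing that
    criterion.
    """

    alive: bool | None = None
    age: float | None = None
    consent: bool | None = None
    dementia_or_psychosis: bool | None = None
    has_contact: bool | None = None
    english_ok: bool | None = None
    active: bool | None = None
    coordinator_approved: bool | None = None


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    self_report: int | None = None  # 1 = veteran, 0 = non-veteran
    metadata: PatientMetadata = field(default_factory=PatientMetadata)

    def __post_init__(self) -> None:
        if self.self_report not in (None, 0, 1):
            raise ValueError(f"self_report must be 0/1/None, got {self.self_report!r}")
        if self.metadata.age is not None and self.metadata.age < 0:
            raise ValueError("age must be non-negative")


@dataclass(frozen=True)
class CohortFlow:
    """One eligibility/recruitment stage: how many entered, how many remained."""

    stage_name: str
    count_in: int
    count_out: int

    def __post_init__(self) -> None:
        if not (0 <= self.count_out <= self.count_in):
            raise ValueError(
                f"stage {self.stage_name!r}: need 0 <= count_out <= count_in, "
                f"got {self.count_out}/{self.count_in}"
            )


_DOC_COLUMNS = ("doc_id", "patient_id", "text")


def read_documents(path: str | Path, format: str | None = None) -> list[ClinicalDocument]:
    """Read a document corpus from JSONL or CSV, preserving file order.

    The format is inferred from the suffix when not given. Duplicate
    ``doc_id`` values raise :class:`CorpusError`.
    """
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    if fmt not in ("jsonl", "csv"):
        raise CorpusError(f"unknown document format {fmt!r}")
    try:
        raw = path.read_text(encoding="utf-8")
    except UnicodeDecodeError as exc:
        raise CorpusError(f"{path} is not valid UTF-8: {exc}") from exc

    rows: list[dict] = []
    if fmt == "jsonl":
        for lineno, line in enumerate(raw.splitlines(), start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            rows.append(obj)
    else:
        reader = csv.DictReader(io.StringIO(raw, newline=""))
        if reader.fieldnames is None:
            return []
        missing = set(_DOC_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise CorpusError(f"{path}: missing columns {sorted(missing)}")
        rows = list(reader)

    docs: list[ClinicalDocument] = []
    seen: set[str] = set()
    for row in rows:
        missing = [k for k in _DOC_COLUMNS if k not in row or row[k] is None]
        if missing:
            raise CorpusError(f"{path}: row missing keys {missing}")
        doc_id = str(row["doc_id"])
        if doc_id in seen:
            raise CorpusError(f"{path}: duplicate doc_id {doc_id!r}")
        seen.add(doc_id)
        created = row.get("created")
        docs.append(
            ClinicalDocument(
                doc_id=doc_id,
                patient_id=str(row["patient_id"]),
                text=str(row["text"]),
                created=str(created) if created not in (None, "") else None,
            )
        )
    return docs


def write_documents(docs: Iterable[ClinicalDocument], path: str | Path,
                    format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for d in docs:
                obj = {"doc_id": d.doc_id, "patient_id": d.patient_id, "text": d.text}
                if d.created is not None:
                    obj["created"] = d.created
                fh.write(json.dumps(obj, ensure_ascii=False) + "\n")
    elif fmt == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow([*_DOC_COLUMNS, "created"])
            for d in docs:
                writer.writerow([d.doc_id, d.patient_id, d.text, d.created or ""])
    else:
        raise CorpusError(f"unknown document format {fmt!r}")


_BOOL_TRUE = {"1", "true", "yes", "y"}
_BOOL_FALSE = {"0", "false", "no", "n"}


def _parse_bool(value: str | None) -> bool | None:
    if value is None or value.strip() == "":
        return None
    v = value.strip().lower()
    if v in _BOOL_TRUE:
        return True
    if v in _BOOL_FALSE:
        return False
    raise CorpusError(f"cannot parse boolean value {value!r}")


def read_patients(path: str | Path) -> list[PatientRecord]:
    """Read patient ground truth and/or metadata from CSV.

    Required column: ``patient_id``. Optional: ``self_report`` plus the
    eligibility attributes (``alive``, ``age``, ``consent``,
    ``dementia_or_psychosis``, ``has_contact``, ``english_ok``, ``active``,
    ``coordinator_approved``). Absent columns and blank cells load as missing.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "patient_id" not in reader.fieldnames:
            raise CorpusError(f"{path}: missing column 'patient_id'")
        records: list[PatientRecord] = []
        seen: set[str] = set()
        for row in reader:
            pid = str(row["patient_id"])
            if pid in seen:
                raise CorpusError(f"{path}: duplicate patient_id {pid!r}")
            seen.add(pid)
            sr_raw = row.get("self_report")
            self_report = int(sr_raw) if sr_raw not in (None, "") else None
            age_raw = row.get("age")
            meta = PatientMetadata(
                alive=_parse_bool(row.get("alive")),
                age=float(age_raw) if age_raw not in (None, "") else None,
                consent=_parse_bool(row.get("consent")),
                dementia_or_psychosis=_parse_bool(row.get("dementia_or_psychosis")),
                has_contact=_parse_bool(row.get("has_contact")),
                english_ok=_parse_bool(row.get("english_ok")),
                active=_parse_bool(row.get("active")),
                coordinator_approved=_parse_bool(row.get("coordinator_approved")),
            )
            records.append(PatientRecord(patient_id=pid, self_report=self_report, metadata=meta))
    return records


def write_patients(patients: Iterable[PatientRecord], path: str | Path) -> None:
    def fmt(value) -> str:
        if value is None:
            return ""
        if isinstance(value, bool):
            return "1" if value else "0"
        return str(value)

    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["patient_id", "self_report", "alive", "age", "consent",
             "dementia_or_psychosis", "has_contact", "english_ok", "active",
             "coordinator_approved"]
        )
        for p in patients:
            m = p.metadata
            writer.writerow(
                [p.patient_id, fmt(p.self_report), fmt(m.alive), fmt(m.age),
                 fmt(m.consent), fmt(m.dementia_or_psychosis), fmt(m.has_contact),
                 fmt(m.english_ok), fmt(m.active), fmt(m.coordinator_approved)]
            )


def write_predictions(decisions, path: str | Path) -> None:
    """Write patient-level predictions as CSV.

    Columns: patient_id, msit_label, n_documents, n_positive_documents.
    """
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "msit_label", "n_documents", "n_positive_documents"])
        for d in decisions:
            writer.writerow([d.patient_id, d.label, d.n_documents, d.n_positive_documents])


def read_predictions(path: str | Path):
    """Read patient-level predictions written by :func:`write_predictions`."""
    from .ml_classifier import PatientDecision

    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"patient_id", "msit_label"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise CorpusError(f"{path}: need columns {sorted(required)}")
        out = []
        for row in reader:
            n_docs = int(row.get("n_documents") or 0)
            n_pos = int(row.get("n_positive_documents") or 0)
            out.append(
                PatientDecision(
                    patient_id=str(row["patient_id"]),
                    label=int(row["msit_label"]),
                    n_documents=n_docs,
                    n_positive_documents=n_pos,
                )
            )
    return out


# Eligibility criteria in screening order: (name, predicate over metadata).
ELIGIBILITY_CRITERIA: tuple[tuple[str, object], ...] = (
    ("alive", lambda m: m.alive is True),
    ("age_18_or_older", lambda m: m.age is not None and m.age >= 18),
    ("consent_given", lambda m: m.consent is True),
    ("no_dementia_or_psychosis", lambda m: m.dementia_or_psychosis is False),
    ("has_email_or_phone", lambda m: m.has_contact is True),
    ("english_without_interpreter", lambda m: m.english_ok is True),
    # Coordinator approval is only required of active patients; a missing
    # 'active' flag is treated conservatively, as if approval were required
    # and absent.
    ("coordinator_approved_if_active",
     lambda m: (m.active is False)
     or (m.active is True and m.coordinator_approved is True)),
)


def filter_eligible(
    patients: Sequence[PatientRecord],
) -> tuple[list[PatientRecord], list[CohortFlow]]:
    """Apply the seven-stage eligibility screen, recording the cohort flow.

    Each stage removes patients failing one criterion; a missing attribute
    fails its criterion. The returned flow has one stage per criterion with
    chained counts, and the eligible list preserves input order.
    """
    current = list(patients)
    flow: list[CohortFlow] = []
    for name, predicate in ELIGIBILITY_CRITERIA:
        count_in = len(current)
        current = [p for p in current if predicate(p.metadata)]
        flow.append(CohortFlow(stage_name=name, count_in=count_in, count_out=len(current)))
    return current, flow
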