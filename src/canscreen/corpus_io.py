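"""Clinical-note corpus I/O: reading, cleaning, and patient-level splits.

Corpora are JSON Lines (one note object per line) or CSV with the columns
note_id, patient_id, note_type, provider_category, date, text. Malformed
records (no note_id or no patient linkage — "orphan" records) are rejected
into an error report rather than aborting the run, and byte-identical
duplicates are collapsed, mirroring routine EHR extract hygiene.
"""

from __future__ import annotations

import csv
import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "ClinicalNote",
    "CorpusSplit",
    "CorpusReadResult",
    "RejectedRecord",
    "DedupResult",
    "NOTE_TYPES",
    "PROVIDER_CATEGORIES",
    "read_corpus",
    "write_corpus",
    "rejections_to_csv",
    "deduplicate",
    "split_by_patient",
    "sample_patients",
]

#: Controlled note-type vocabulary (extensible); canonical casing.
NOTE_TYPES = (
    "Plan of Care",
    "Not Specified",
    "Nursing",
    "Emergency Department Notes",
    "Patient Instructions",
    "ED AVS Snapshot",
    "Telephone Encounter",
    "MR AVS Snapshot",
    "Letter",
    "Medical Student",
    "Discharge Instructions - Other Orders",
    "Sticky Note",
    "Emergency Department Provider Notes",
    "Progress Notes",
    "IP AVS Snapshot",
    "Discharge Summaries",
    "H&P",
    "Lactation Note",
    "Consults",
    "Consult NW",
    "Social Worker/Case Management",
    "Treatment Plan",
)

PROVIDER_CATEGORIES = ("physician", "nurse", "social_worker", "other", "unknown")

_CANONICAL_TYPES = {t.lower(): t for t in NOTE_TYPES}

_CSV_COLUMNS = ("note_id", "patient_id", "note_type", "provider_category", "date", "text")


def _canonical_note_type(raw: Optional[str]) -> str:
    if raw is None or not str(raw).strip():
        return "Not Specified"
    cleaned = " ".join(str(raw).split())
    return _CANONICAL_TYPES.get(cleaned.lower(), cleaned)


@dataclass(frozen=True)
class ClinicalNote:
    """One clinical note with typed metadata; ``text`` may be empty."""

    note_id: str
    patient_id: str
    note_type: str = "Not Specified"
    provider_category: str = "unknown"
    date: str = ""
    text: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "note_type", _canonical_note_type(self.note_type))
        if self.provider_category not in PROVIDER_CATEGORIES:
            object.__setattr__(self, "provider_category", "unknown")


@dataclass(frozen=True)
class RejectedRecord:
    line_no: int
    reason: str
    raw: str


@dataclass(frozen=True)
class CorpusReadResult:
    notes: tuple[ClinicalNote, ...]
    rejected: tuple[RejectedRecord, ...]
    empty_text_ids: tuple[str, ...]


def _validate_record(record: dict, line_no: int, seen_ids: set[str]):
    note_id = str(record.get("note_id") or "").strip()
    patient_id = str(record.get("patient_id") or "").strip()
    if not note_id:
        return None, RejectedRecord(line_no, "missing note_id", json.dumps(record))
    if not patient_id:
        return None, RejectedRecord(
            line_no, "orphan record: missing patient_id", json.dumps(record)
        )
    if note_id in seen_ids:
        return None, RejectedRecord(line_no, f"duplicate note_id {note_id!r}", json.dumps(record))
    note = ClinicalNote(
        note_id=note_id,
        patient_id=patient_id,
        note_type=record.get("note_type") or "",
        provider_category=str(record.get("provider_category") or "unknown"),
        date=str(record.get("date") or ""),
        text=str(record.get("text") if record.get("text") is not None else ""),
    )
    return note, None


def read_corpus(path: str | Path, format: Optional[str] = None) -> CorpusReadResult:
    """Read and validate a corpus; malformed lines go to the rejection report.

    ``format`` is "jsonl" or "csv"; inferred from the file suffix when None.
    JSONL and CSV encodings of the same notes parse identically.
    """
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    notes: list[ClinicalNote] = []
    rejected: list[RejectedRecord] = []
    seen: set[str] = set()
    if fmt == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for line_no, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    record = json.loads(line)
                except json.JSONDecodeError as exc:
                    rejected.append(RejectedRecord(line_no, f"invalid JSON: {exc}", line.strip()))
                    continue
                note, rej = _validate_record(record, line_no, seen)
                if note:
                    seen.add(note.note_id)
                    notes.append(note)
                else:
                    rejected.append(rej)
    elif fmt == "csv":
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for line_no, record in enumerate(reader, start=2):
                note, rej = _validate_record(record, line_no, seen)
                if note:
                    seen.add(note.note_id)
                    notes.append(note)
                else:
                    rejected.append(rej)
    else:
        raise ValueError(f"unknown corpus format {fmt!r} (expected 'jsonl' or 'csv')")
    empty = tuple(n.note_id for n in notes if not n.text.strip())
    return CorpusReadResult(tuple(notes), tuple(rejected), empty)


def write_corpus(notes: Iterable[ClinicalNote], path: str | Path, format: Optional[str] = None) -> None:
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    if fmt == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for n in notes:
                fh.write(json.dumps({c: getattr(n, c) for c in _CSV_COLUMNS}, ensure_ascii=False))
                fh.write("\n")
    elif fmt == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS, lineterminator="\n")
            writer.writeheader()
            for n in notes:
                writer.writerow({c: getattr(n, c) for c in _CSV_COLUMNS})
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")


def rejections_to_csv(rejected: Sequence[RejectedRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["line_no", "reason", "raw"])
        for r in rejected:
            writer.writerow([r.line_no, r.reason, r.raw])


@dataclass(frozen=True)
class DedupResult:
    notes: tuple[ClinicalNote, ...]
    n_removed: int


def deduplicate(notes: Sequence[ClinicalNote]) -> DedupResult:
    """Collapse notes with identical (patient_id, note_type, text) to the
    earliest-dated instance (ties broken by note_id). Idempotent."""
    best: dict[tuple[str, str, str], ClinicalNote] = {}
    for n in notes:
        key = (n.patient_id, n.note_type, n.text)
        cur = best.get(key)
        if cur is None or (n.date, n.note_id) < (cur.date, cur.note_id):
            best[key] = n
    keep_ids = {n.note_id for n in best.values()}
    kept = tuple(n for n in notes if n.note_id in keep_ids)
    return DedupResult(kept, len(notes) - len(kept))


@dataclass(frozen=True)
class CorpusSplit:
    """Disjoint patient-level train/test partition."""

    train_patients: frozenset[str]
    test_patients: frozenset[str]
    seed: int

    def __post_init__(self) -> None:
        if self.train_patients & self.test_patients:
            raise ValueError("train and test patient sets overlap")

    def train_notes(self, notes: Sequence[ClinicalNote]) -> list[ClinicalNote]:
        return [n for n in notes if n.patient_id in self.train_patients]

    def test_notes(self, notes: Sequence[ClinicalNote]) -> list[ClinicalNote]:
        return [n for n in notes if n.patient_id in self.test_patients]


def split_by_patient(
    notes: Sequence[ClinicalNote], train_frac: float = 0.75, seed: int = 0
) -> CorpusSplit:
    """Seeded patient-level split; every note follows its patient.

    Patients are shuffled with the given seed and the first
    ``ceil(train_frac * P)`` go to the training partition.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError(f"train_frac must lie in (0, 1), got {train_frac}")
    patients = sorted({n.patient_id for n in notes})
    if len(patients) < 2:
        raise ValueError("need at least 2 patients to split")
    rng = random.Random(seed)
    rng.shuffle(patients)
    n_train = math.ceil(train_frac * len(patients))
    return CorpusSplit(frozenset(patients[:n_train]), frozenset(patients[n_train:]), seed)


def sample_patients(
    notes: Sequence[ClinicalNote], n: int, seed: int = 0
) -> list[ClinicalNote]:
    """All notes of a seeded uniform sample of ``n`` patients (no replacement)."""
    patients = sorted({note.patient_id for note in notes})
    if n > len(patients):
        raise ValueError(f"cannot sample {n} of {len(patients)} patients")
    chosen = set(random.Random(seed).sample(patients, n))
    return [note for note in notes if note.patient_id in chosen]
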