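"""Shared domain types and flat-file readers/writers.

The pipeline passes three kinds of artifacts between stages: clinical notes
(JSONL, one document per line), label tables (CSV, one row per sentence, note
or patient) and demographics (CSV).  All types are plain dataclasses; label
CSVs round-trip bit-exactly through :func:`write_labels` / :func:`read_labels`.

Conventions: character offsets are 0-based half-open; dates are ISO 8601 and
only the year component enters age arithmetic.
"""

from __future__ import annotations

import csv
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

# --------------------------------------------------------------------------
# Controlled vocabularies

BEHAVIOR_CLASSES = ("B1", "B2", "B3")
#: severity order used by every aggregation step: B1 < B2 < B3
BEHAVIOR_SEVERITY = {"B1": 1, "B2": 2, "B3": 3}

BINARY_POSITIVE = "B2/B3"
BINARY_NEGATIVE = "Not B2/B3"

MENTION_CATEGORIES = ("B2", "B3", "perianal")
MATCH_ROUTES = ("string", "concept")
ASSERTIONS = ("asserted", "negated")
LABEL_SOURCES = ("rules", "llm", "ensemble_and", "ensemble_or", "gold")
MONTREAL_AGE_CLASSES = ("A1", "A2", "A3")


def behavior_binary(behavior: str) -> str:
    """Collapse a Montreal behavior class to the complication dichotomy."""
    if behavior not in BEHAVIOR_CLASSES:
        raise ValueError(f"unknown behavior class: {behavior!r}")
    return BINARY_POSITIVE if behavior in ("B2", "B3") else BINARY_NEGATIVE


def max_severity(behaviors: Iterable[str]) -> str:
    """Most severe class under B1 < B2 < B3; B1 when the iterable is empty."""
    best = "B1"
    for b in behaviors:
        if b not in BEHAVIOR_SEVERITY:
            raise ValueError(f"unknown behavior class: {b!r}")
        if BEHAVIOR_SEVERITY[b] > BEHAVIOR_SEVERITY[best]:
            best = b
    return best


# --------------------------------------------------------------------------
# Errors


class DataModelError(Exception):
    """Base class for data-layer failures."""


class NoteRecordError(DataModelError):
    """A malformed JSONL note record; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number
        self.message = message


class LabelFileError(DataModelError):
    """Label CSV does not conform to the level's schema."""


# --------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class ClinicalNote:
    """One timestamped free-text document tied to a patient."""

    patient_id: str
    note_id: str
    note_datetime: datetime.date
    note_type: str
    text: str

    @property
    def note_year(self) -> int:
        return self.note_datetime.year


@dataclass(frozen=True)
class Sentence:
    """A contiguous span of a note, addressed by 0-based half-open offsets."""

    note_id: str
    index: int
    char_start: int
    char_end: int
    text: str

    def validate_against(self, note: ClinicalNote) -> None:
        if self.note_id != note.note_id:
            raise ValueError("sentence does not belong to this note")
        if not (0 <= self.char_start < self.char_end <= len(note.text)):
            raise ValueError(
                f"offsets [{self.char_start}, {self.char_end}) outside note "
                f"of length {len(note.text)}"
            )
        if note.text[self.char_start : self.char_end] != self.text:
            raise ValueError("sentence text does not match note span")


@dataclass(frozen=True)
class PhenotypeMention:
    """One matched complication term inside a sentence (evidence atom)."""

    note_id: str
    sentence_index: int
    char_start: int  # offsets relative to the sentence text
    char_end: int
    matched_text: str
    category: str  # B2 | B3 | perianal
    match_route: str  # string | concept
    assertion: Optional[str] = None  # asserted | negated; set downstream
    excluded_by_context: bool = False
    implies_behavior: Optional[str] = None  # perianal complication → B3

    def __post_init__(self):
        if self.category not in MENTION_CATEGORIES:
            raise ValueError(f"unknown mention category: {self.category!r}")
        if self.match_route not in MATCH_ROUTES:
            raise ValueError(f"unknown match route: {self.match_route!r}")
        if self.assertion is not None and self.assertion not in ASSERTIONS:
            raise ValueError(f"unknown assertion: {self.assertion!r}")


@dataclass(frozen=True)
class SentenceLabel:
    """Per-sentence evidence: which complication classes are asserted here."""

    note_id: str
    sentence_index: int
    behavior_evidence: frozenset = frozenset()  # subset of {"B2", "B3"}
    perianal: bool = False

    def __post_init__(self):
        extra = set(self.behavior_evidence) - {"B2", "B3"}
        if extra:
            raise ValueError(f"behavior evidence outside {{B2,B3}}: {extra}")


@dataclass(frozen=True)
class NoteLabel:
    """Aggregated behavior class for one note, with provenance."""

    patient_id: str
    note_id: str
    note_datetime: datetime.date
    behavior: str
    perianal: bool
    source: str
    evidence: tuple = ()  # contributing sentence indices; empty for llm/gold

    def __post_init__(self):
        if self.behavior not in BEHAVIOR_CLASSES:
            raise ValueError(f"unknown behavior class: {self.behavior!r}")
        if self.source not in LABEL_SOURCES:
            raise ValueError(f"unknown label source: {self.source!r}")

    @property
    def behavior_binary(self) -> str:
        return behavior_binary(self.behavior)


@dataclass(frozen=True)
class PatientLabel:
    """Patient-level roll-up: maximal behavior, perianal modifier, age."""

    patient_id: str
    behavior: Optional[str]
    perianal: Optional[bool]
    source: str
    age_at_diagnosis: Optional[float] = None
    montreal_age: Optional[str] = None

    def __post_init__(self):
        if self.behavior is not None and self.behavior not in BEHAVIOR_CLASSES:
            raise ValueError(f"unknown behavior class: {self.behavior!r}")
        if self.source not in LABEL_SOURCES:
            raise ValueError(f"unknown label source: {self.source!r}")
        if self.montreal_age is not None:
            if self.montreal_age not in MONTREAL_AGE_CLASSES:
                raise ValueError(f"unknown Montreal age class: {self.montreal_age!r}")
            if self.age_at_diagnosis is None:
                raise ValueError("montreal_age set without age_at_diagnosis")

    @property
    def behavior_binary(self) -> Optional[str]:
        return None if self.behavior is None else behavior_binary(self.behavior)


@dataclass(frozen=True)
class AgeEvidence:
    """One extracted age-at-diagnosis statement, not yet resolved to years."""

    note_id: str
    sentence_index: int
    kind: str  # direct_age | diagnosis_year | duration
    raw_value: float
    raw_unit: Optional[str] = None  # years | months; duration only
    char_start: int = 0
    char_end: int = 0

    def __post_init__(self):
        if self.kind not in ("direct_age", "diagnosis_year", "duration"):
            raise ValueError(f"unknown age evidence kind: {self.kind!r}")
        if self.kind == "duration":
            if self.raw_unit not in ("years", "months"):
                raise ValueError("duration evidence needs raw_unit years|months")
            if self.raw_value < 0:
                raise ValueError("duration must be non-negative")
        elif self.raw_unit is not None:
            raise ValueError(f"{self.kind} evidence takes no unit")
        if self.kind == "direct_age" and not (0 <= self.raw_value <= 120):
            raise ValueError("direct age outside [0, 120]")


@dataclass(frozen=True)
class ReferenceContext:
    """Temporal anchor for resolving year/duration statements to an age.

    Only year arithmetic is performed, so a ±1-year margin is inherent: exact
    birth dates are rarely written in notes.  When both ``age_at_reference``
    and ``birth_year`` are supplied they must agree within that margin.
    """

    reference_year: int
    age_at_reference: Optional[float] = None
    birth_year: Optional[int] = None

    def __post_init__(self):
        if self.age_at_reference is not None and self.birth_year is not None:
            gap = abs(self.reference_year - self.birth_year - self.age_at_reference)
            if gap > 1:
                raise ValueError(
                    f"inconsistent context: reference_year - birth_year differs "
                    f"from age_at_reference by {gap:.1f} (> 1) years"
                )


@dataclass(frozen=True)
class AgeResult:
    """A resolved age at diagnosis for one note or one patient."""

    scope: str  # note | patient
    id: str
    age_at_diagnosis: float
    evidence: tuple = ()
    discordant: bool = False

    def __post_init__(self):
        if self.scope not in ("note", "patient"):
            raise ValueError(f"unknown age result scope: {self.scope!r}")
        if not (0 <= self.age_at_diagnosis <= 120):
            raise ValueError("age_at_diagnosis outside [0, 120]")


# --------------------------------------------------------------------------
# Notes I/O (JSONL)

_REQUIRED_NOTE_FIELDS = ("patient_id", "note_id", "note_datetime", "note_type", "text")


def _parse_note_record(obj: dict, line_number: int) -> ClinicalNote:
    for f in _REQUIRED_NOTE_FIELDS:
        if f not in obj:
            raise NoteRecordError(line_number, f"missing required field {f!r}")
    try:
        date = datetime.date.fromisoformat(str(obj["note_datetime"]))
    except ValueError:
        raise NoteRecordError(
            line_number, f"unparseable note_datetime {obj['note_datetime']!r}"
        ) from None
    return ClinicalNote(
        patient_id=str(obj["patient_id"]),
        note_id=str(obj["note_id"]),
        note_datetime=date,
        note_type=str(obj["note_type"]),
        text=str(obj["text"]),
    )


def read_notes(
    path: Union[str, Path], on_malformed: str = "error"
) -> Union[list, tuple]:
    """Read a JSONL note file.

    With ``on_malformed="error"`` (default) the first malformed line raises a
    :class:`NoteRecordError` naming the line and the offending field.  With
    ``"collect"`` returns ``(notes, errors)`` where ``errors`` is a list of
    :class:`NoteRecordError`, so a corpus with a few bad lines is still usable.
    """
    if on_malformed not in ("error", "collect"):
        raise ValueError("on_malformed must be 'error' or 'collect'")
    notes, errors = [], []
    seen_ids = set()
    with open(path, encoding="utf-8") as fh:
        for line_number, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                if not isinstance(obj, dict):
                    raise NoteRecordError(line_number, "record is not a JSON object")
                note = _parse_note_record(obj, line_number)
                if note.note_id in seen_ids:
                    raise NoteRecordError(
                        line_number, f"duplicate note_id {note.note_id!r}"
                    )
            except json.JSONDecodeError as exc:
                err = NoteRecordError(line_number, f"invalid JSON: {exc.msg}")
                if on_malformed == "error":
                    raise err from None
                errors.append(err)
                continue
            except NoteRecordError as err:
                if on_malformed == "error":
                    raise
                errors.append(err)
                continue
            seen_ids.add(note.note_id)
            notes.append(note)
    if on_malformed == "collect":
        return notes, errors
    return notes


def write_notes(notes: Sequence[ClinicalNote], path: Union[str, Path]) -> None:
    """Write notes as JSONL (sorted keys, so output is byte-stable)."""
    with open(path, "w", encoding="utf-8") as fh:
        for n in notes:
            fh.write(
                json.dumps(
                    {
                        "patient_id": n.patient_id,
                        "note_id": n.note_id,
                        "note_datetime": n.note_datetime.isoformat(),
                        "note_type": n.note_type,
                        "text": n.text,
                    },
                    sort_keys=True,
                    ensure_ascii=False,
                )
                + "\n"
            )


# --------------------------------------------------------------------------
# Label I/O (CSV)

LABEL_COLUMNS = {
    "sentence": ("note_id", "sentence_index", "behavior_evidence", "perianal"),
    "note": (
        "patient_id",
        "note_id",
        "note_datetime",
        "behavior",
        "behavior_binary",
        "perianal",
        "source",
        "evidence",
    ),
    "patient": (
        "patient_id",
        "behavior",
        "behavior_binary",
        "perianal",
        "age_at_diagnosis",
        "montreal_age",
        "source",
    ),
}

_LEVEL_TYPES = {"sentence": SentenceLabel, "note": NoteLabel, "patient": PatientLabel}


def _fmt_bool(v: Optional[bool]) -> str:
    if v is None:
        return ""
    return "yes" if v else "no"


def _parse_bool(s: str) -> Optional[bool]:
    if s == "":
        return None
    if s not in ("yes", "no"):
        raise LabelFileError(f"expected yes/no, got {s!r}")
    return s == "yes"


def _fmt_age(v: Optional[float]) -> str:
    return "" if v is None else repr(float(v))


def _label_row(label, level: str) -> list:
    if level == "sentence":
        return [
            label.note_id,
            str(label.sentence_index),
            "|".join(sorted(label.behavior_evidence)),
            _fmt_bool(label.perianal),
        ]
    if level == "note":
        return [
            label.patient_id,
            label.note_id,
            label.note_datetime.isoformat(),
            label.behavior,
            label.behavior_binary,
            _fmt_bool(label.perianal),
            label.source,
            ";".join(str(i) for i in label.evidence),
        ]
    return [
        label.patient_id,
        label.behavior or "",
        label.behavior_binary or "",
        _fmt_bool(label.perianal),
        _fmt_age(label.age_at_diagnosis),
        label.montreal_age or "",
        label.source,
    ]


def write_labels(labels: Sequence, path: Union[str, Path], level: str) -> None:
    """Write a homogeneous list of labels as CSV with a fixed column order."""
    if level not in LABEL_COLUMNS:
        raise ValueError(f"unknown label level: {level!r}")
    expected = _LEVEL_TYPES[level]
    for lab in labels:
        if not isinstance(lab, expected):
            raise LabelFileError(
                f"level {level!r} expects {expected.__name__}, "
                f"got {type(lab).__name__}"
            )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(LABEL_COLUMNS[level])
        for lab in labels:
            writer.writerow(_label_row(lab, level))


def read_labels(path: Union[str, Path], level: str) -> list:
    """Inverse of :func:`write_labels`."""
    if level not in LABEL_COLUMNS:
        raise ValueError(f"unknown label level: {level!r}")
    out = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or tuple(header) != LABEL_COLUMNS[level]:
            raise LabelFileError(
                f"unexpected header for level {level!r}: {header}"
            )
        for row in reader:
            rec = dict(zip(header, row))
            if level == "sentence":
                ev = rec["behavior_evidence"]
                out.append(
                    SentenceLabel(
                        note_id=rec["note_id"],
                        sentence_index=int(rec["sentence_index"]),
                        behavior_evidence=frozenset(ev.split("|")) if ev else frozenset(),
                        perianal=_parse_bool(rec["perianal"]),
                    )
                )
            elif level == "note":
                ev = rec["evidence"]
                out.append(
                    NoteLabel(
                        patient_id=rec["patient_id"],
                        note_id=rec["note_id"],
                        note_datetime=datetime.date.fromisoformat(rec["note_datetime"]),
                        behavior=rec["behavior"],
                        perianal=_parse_bool(rec["perianal"]),
                        source=rec["source"],
                        evidence=tuple(int(i) for i in ev.split(";")) if ev else (),
                    )
                )
            else:
                out.append(
                    PatientLabel(
                        patient_id=rec["patient_id"],
                        behavior=rec["behavior"] or None,
                        perianal=_parse_bool(rec["perianal"]),
                        age_at_diagnosis=(
                            float(rec["age_at_diagnosis"])
                            if rec["age_at_diagnosis"]
                            else None
                        ),
                        montreal_age=rec["montreal_age"] or None,
                        source=rec["source"],
                    )
                )
    return out


# --------------------------------------------------------------------------
# Demographics I/O


@dataclass(frozen=True)
class Demographics:
    patient_id: str
    birth_year: Optional[int]
    enrollment_year: Optional[int]


def read_demographics(path: Union[str, Path]) -> dict:
    """Read demographics CSV → dict patient_id → :class:`Demographics`."""
    out = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            pid = row["patient_id"]
            out[pid] = Demographics(
                patient_id=pid,
                birth_year=int(row["birth_year"]) if row.get("birth_year") else None,
                enrollment_year=(
                    int(row["enrollment_year"]) if row.get("enrollment_year") else None
                ),
            )
    return out


def write_demographics(demo: Iterable[Demographics], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["patient_id", "birth_year", "enrollment_year"])
        for d in demo:
            writer.writerow(
                [
                    d.patient_id,
                    "" if d.birth_year is None else d.birth_year,
                    "" if d.enrollment_year is None else d.enrollment_year,
                ]
            )
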