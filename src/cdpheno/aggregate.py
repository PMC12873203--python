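"""Deterministic roll-up of labels from sentence → note → patient.

Behavior aggregates under the severity order B1 < B2 < B3 (B1 is the
closed-world default when no complication evidence exists anywhere);
perianal disease is an independent modifier ("yes" if any evidence); age at
diagnosis takes the earliest value across notes.  Both roll-ups are
order-independent and idempotent, and adding a note can only raise severity
or lower the diagnosis age — never the reverse.
"""

from __future__ import annotations

import datetime
import logging
import math
from typing import Mapping, Optional, Sequence

from .data_model import (
    AgeResult,
    ClinicalNote,
    NoteLabel,
    PatientLabel,
    SentenceLabel,
    max_severity,
)

logger = logging.getLogger(__name__)


def aggregate_note(
    sentence_labels: Sequence[SentenceLabel],
    note: ClinicalNote,
    source: str = "rules",
) -> NoteLabel:
    """Roll sentence evidence up to one note label.

    behavior = most severe class among the sentence evidence sets (B1 when
    none); perianal = yes iff any sentence flags it; `evidence` lists the
    indices of contributing sentences; the note timestamp is carried through.
    """
    foreign = {s.note_id for s in sentence_labels} - {note.note_id}
    if foreign:
        raise ValueError(f"sentence labels from other notes: {sorted(foreign)}")
    evidence_classes = []
    contributing = set()
    perianal = False
    for s in sentence_labels:
        if s.behavior_evidence:
            evidence_classes.extend(s.behavior_evidence)
            contributing.add(s.sentence_index)
        if s.perianal:
            perianal = True
            contributing.add(s.sentence_index)
    return NoteLabel(
        patient_id=note.patient_id,
        note_id=note.note_id,
        note_datetime=note.note_datetime,
        behavior=max_severity(evidence_classes),
        perianal=perianal,
        source=source,
        evidence=tuple(sorted(contributing)),
    )


def montreal_age_category(age: float) -> str:
    """Montreal A-class for a diagnosis age: A1 ≤ 16, A2 17–40, A3 > 40.

    Fractional ages are floored first, so 16.5 years is still A1.
    """
    if not (0 <= age <= 120):
        raise ValueError(f"age {age} outside [0, 120]")
    whole = math.floor(age)
    if whole <= 16:
        return "A1"
    if whole <= 40:
        return "A2"
    return "A3"


def aggregate_patient(
    note_labels: Sequence[NoteLabel],
    age_results: Sequence[AgeResult] = (),
    cutoff_date: Optional[datetime.date] = None,
    age_result_dates: Optional[Mapping[str, datetime.date]] = None,
    source: str = "rules",
) -> PatientLabel:
    """Roll note labels and note-level ages up to one patient label.

    Only notes dated on or before ``cutoff_date`` (e.g. study enrollment)
    are considered when a cutoff is given; by default every note counts,
    matching note-level experiments.  ``age_result_dates`` maps note_id →
    note date so the same cutoff applies to age evidence.  A patient whose
    notes all fall after the cutoff is emitted with null fields and a
    warning rather than dropped.
    """
    pids = {n.patient_id for n in note_labels}
    if len(pids) > 1:
        raise ValueError(f"note labels from multiple patients: {sorted(pids)}")
    patient_id = next(iter(pids)) if pids else ""

    usable = [
        n
        for n in note_labels
        if cutoff_date is None or n.note_datetime <= cutoff_date
    ]
    usable_ages = [
        a
        for a in age_results
        if cutoff_date is None
        or age_result_dates is None
        or a.id not in age_result_dates
        or age_result_dates[a.id] <= cutoff_date
    ]
    if not usable:
        logger.warning(
            "patient %s has no notes on or before cutoff %s", patient_id, cutoff_date
        )
        return PatientLabel(
            patient_id=patient_id, behavior=None, perianal=None, source=source
        )
    age = min((a.age_at_diagnosis for a in usable_ages), default=None)
    return PatientLabel(
        patient_id=patient_id,
        behavior=max_severity(n.behavior for n in usable),
        perianal=any(n.perianal for n in usable),
        source=source,
        age_at_diagnosis=age,
        montreal_age=None if age is None else montreal_age_category(age),
    )
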