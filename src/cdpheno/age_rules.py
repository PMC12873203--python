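"""Age-at-diagnosis extraction and resolution.

Clinical notes state the age at initial Crohn's diagnosis in three surface
forms, each handled by its own pattern group:

1. directly stated age   — "diagnosed with Crohn's at age 25";
2. year of diagnosis     — "Crohn's disease since 2005";
3. disease duration      — "18-month history of Crohn's disease".

A year or duration statement is resolved against a :class:`ReferenceContext`
(the note year or enrollment year plus the patient's age or birth year at
that reference).  All arithmetic is year-granular; exact dates are rarely
written, so every downstream comparison carries a ±1-year tolerance.
Fractional ages from month durations are kept unrounded — rounding would
double-count that margin.  Vague decade statements ("diagnosed in his 20s")
are deliberately not extracted: they cannot be resolved to ±1 year.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .data_model import AgeEvidence, AgeResult, ReferenceContext, Sentence

logger = logging.getLogger(__name__)


class AgeResolutionError(ValueError):
    """Context lacks a field the evidence kind requires; names the field."""

    def __init__(self, field: str, kind: str):
        super().__init__(f"resolving {kind} evidence requires context field {field!r}")
        self.field = field


class AgeRangeError(ValueError):
    """Resolved age falls outside the plausible [0, 120] range."""


# --------------------------------------------------------------------------
# Pattern set


@dataclass(frozen=True)
class AgePattern:
    kind: str  # direct_age | diagnosis_year | duration
    regex: str
    value_group: int = 1
    unit_group: Optional[int] = None  # duration patterns only

    def compiled(self):
        return re.compile(self.regex, re.IGNORECASE)


DEFAULT_AGE_PATTERNS: Tuple[AgePattern, ...] = (
    # (1) directly stated age
    AgePattern(
        "direct_age",
        r"diagnos\w*[^.;]{0,40}?\bat\s+(?:the\s+)?age\s+(?:of\s+)?(\d{1,3})\b",
    ),
    AgePattern("direct_age", r"diagnos\w*\s+at\s+(\d{1,3})\b(?!\s*(?:year|month))"),
    AgePattern("direct_age", r"\bage\s+at\s+diagnosis[:\s]+(\d{1,3})\b"),
    AgePattern(
        "direct_age",
        r"\bat\s+age\s+(\d{1,3})\b[^.;]{0,40}?diagnos\w*",
    ),
    # (2) year of diagnosis
    AgePattern("diagnosis_year", r"diagnos\w*[^.;]{0,40}?\bin\s+((?:19|20)\d{2})\b"),
    AgePattern(
        "diagnosis_year",
        r"crohn'?s?[^.;]{0,60}?\bsince\s+((?:19|20)\d{2})\b",
    ),
    AgePattern("diagnosis_year", r"\b(?:cd|ibd)\s+since\s+((?:19|20)\d{2})\b"),
    # (3) disease duration
    AgePattern(
        "duration",
        r"(\d{1,3})[-\s](year|month)s?\s+history\s+of\s+(?:crohn|cd\b|ibd\b)",
        unit_group=2,
    ),
    AgePattern(
        "duration",
        r"crohn'?s?[^.;]{0,40}?\bfor\s+(?:the\s+past\s+)?(\d{1,3})\s+(year|month)s?\b",
        unit_group=2,
    ),
    AgePattern(
        "duration",
        r"(\d{1,3})\s+(year|month)s?\s+of\s+crohn",
        unit_group=2,
    ),
)


@dataclass(frozen=True)
class AgePatternSet:
    patterns: Tuple[AgePattern, ...] = DEFAULT_AGE_PATTERNS

    def __post_init__(self):
        for p in self.patterns:
            if p.kind not in ("direct_age", "diagnosis_year", "duration"):
                raise ValueError(f"unknown pattern kind: {p.kind!r}")
            p.compiled()  # raises re.error on an invalid pattern
            if p.kind == "duration" and p.unit_group is None:
                raise ValueError("duration patterns must set unit_group")


# --------------------------------------------------------------------------
# Extraction


def extract_age_evidence(
    sentence: Sentence,
    patterns: AgePatternSet = AgePatternSet(),
    note_year: Optional[int] = None,
) -> List[AgeEvidence]:
    """All age-at-diagnosis statements matched in one sentence.

    Values violating the evidence invariants (direct age outside [0, 120],
    diagnosis year before 1900 or after the note year) are discarded with a
    log entry rather than raised — a single garbled number must not abort a
    note.  Duplicate hits of the same kind on the same span are collapsed.
    """
    found = {}
    for pat in patterns.patterns:
        for m in pat.compiled().finditer(sentence.text):
            value = float(m.group(pat.value_group))
            unit = None
            if pat.unit_group is not None:
                unit = m.group(pat.unit_group).lower() + "s"
            span = (m.start(pat.value_group), m.end(pat.value_group))
            key = (pat.kind, span)
            if key in found:
                continue
            if pat.kind == "direct_age" and not (0 <= value <= 120):
                logger.warning(
                    "discarding implausible direct age %s in %s[%d]",
                    value, sentence.note_id, sentence.index,
                )
                continue
            if pat.kind == "diagnosis_year":
                upper = note_year if note_year is not None else 2100
                if not (1900 <= value <= upper):
                    logger.warning(
                        "discarding implausible diagnosis year %s in %s[%d]",
                        value, sentence.note_id, sentence.index,
                    )
                    continue
            found[key] = AgeEvidence(
                note_id=sentence.note_id,
                sentence_index=sentence.index,
                kind=pat.kind,
                raw_value=value,
                raw_unit=unit,
                char_start=span[0],
                char_end=span[1],
            )
    return sorted(found.values(), key=lambda e: (e.char_start, e.kind))


# --------------------------------------------------------------------------
# Resolution


def resolve_age(evidence: AgeEvidence, context: ReferenceContext) -> float:
    """Resolve one evidence item to an age in years.

    direct_age     → the stated value;
    diagnosis_year → age_at_reference − (reference_year − year), or
                     year − birth_year when only the birth year is known
                     (the two coincide when the context is exactly
                     consistent);
    duration       → age_at_reference − duration, months converted to
                     fractional years.
    """
    if evidence.kind == "direct_age":
        age = evidence.raw_value
    elif evidence.kind == "diagnosis_year":
        if context.age_at_reference is not None:
            age = context.age_at_reference - (
                context.reference_year - evidence.raw_value
            )
        elif context.birth_year is not None:
            age = evidence.raw_value - context.birth_year
        else:
            raise AgeResolutionError("age_at_reference", evidence.kind)
    else:  # duration
        if context.age_at_reference is None:
            raise AgeResolutionError("age_at_reference", evidence.kind)
        years = (
            evidence.raw_value / 12.0
            if evidence.raw_unit == "months"
            else evidence.raw_value
        )
        age = context.age_at_reference - years
    if not (0 <= age <= 120):
        raise AgeRangeError(
            f"resolved age {age:.1f} outside [0, 120] "
            f"({evidence.kind} evidence in {evidence.note_id})"
        )
    return float(age)


def resolve_note_age(
    evidences: Sequence[AgeEvidence], context: ReferenceContext
) -> Optional[AgeResult]:
    """Resolve all evidence of one note into a single note-level age.

    Per-evidence resolution errors are logged and skipped, never abort the
    note.  When the resolvable values disagree by more than 1 year the note
    is flagged discordant; the minimum (earliest diagnosis age) is returned
    either way, mirroring the patient-level earliest-age rule.
    """
    note_ids = {e.note_id for e in evidences}
    if len(note_ids) > 1:
        raise ValueError(f"evidence from multiple notes: {sorted(note_ids)}")
    resolved = []
    used = []
    for ev in evidences:
        try:
            resolved.append(resolve_age(ev, context))
            used.append(ev)
        except (AgeResolutionError, AgeRangeError) as exc:
            logger.warning("skipping evidence in %s: %s", ev.note_id, exc)
    if not resolved:
        return None
    return AgeResult(
        scope="note",
        id=next(iter(note_ids)),
        age_at_diagnosis=min(resolved),
        evidence=tuple(used),
        discordant=(max(resolved) - min(resolved)) > 1.0,
    )
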