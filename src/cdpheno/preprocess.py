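"""Corpus filtering and sentence segmentation.

Three steps run before any phenotype extraction:

1. :func:`filter_notes` — drop empty notes, administrative note types
   (telephone encounters, patient instructions, ...) and notes without any
   Crohn's/IBD context term, logging one reason per dropped note.
2. :func:`segment_sentences` — deterministic rule-based splitting into
   offset-addressed sentences.  A shipped abbreviation list ("Dr.",
   "b.i.d.", "vs.", ...) prevents spurious breaks; the contract that is
   fixed is the offsets and the no-break list, not the engine.
3. :func:`prefilter_age_notes` — cheap regex prefilter that keeps only notes
   plausibly containing an age-at-diagnosis statement ("diagnosed",
   "Crohn's ... since", "age at", ...), run before the more expensive age
   extraction patterns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

from .data_model import ClinicalNote, Sentence

# --------------------------------------------------------------------------
# Configuration

DEFAULT_EXCLUDED_NOTE_TYPES = frozenset(
    {
        "telephone encounter",
        "patient instructions",
        "scheduling note",
        "billing note",
    }
)

#: case-insensitive regexes; one hit anywhere in the note keeps it
DEFAULT_DISEASE_CONTEXT_TERMS = (
    r"crohn",
    r"\bibd\b",
    r"inflammatory bowel",
    r"ileocolitis",
    r"\bcd\b",
)

DEFAULT_AGE_PREFILTER_PATTERNS = (
    r"diagnos",
    r"crohn.{0,60}since",
    r"\bage at\b",
    r"history of crohn",
    r"crohn.{0,60}\bfor\s+\d",
)

DEFAULT_ABBREVIATIONS = frozenset(
    {
        "dr.",
        "mr.",
        "mrs.",
        "ms.",
        "prof.",
        "st.",
        "vs.",
        "approx.",
        "e.g.",
        "i.e.",
        "etc.",
        "b.i.d.",
        "t.i.d.",
        "q.d.",
        "q.i.d.",
        "p.r.n.",
        "p.o.",
        "s/p.",
    }
)


@dataclass(frozen=True)
class PreprocessConfig:
    excluded_note_types: frozenset = DEFAULT_EXCLUDED_NOTE_TYPES
    disease_context_terms: Tuple[str, ...] = DEFAULT_DISEASE_CONTEXT_TERMS
    age_prefilter_patterns: Tuple[str, ...] = DEFAULT_AGE_PREFILTER_PATTERNS
    abbreviations: frozenset = DEFAULT_ABBREVIATIONS

    def __post_init__(self):
        if not self.excluded_note_types:
            raise ValueError("excluded_note_types must be non-empty")
        if not self.disease_context_terms:
            raise ValueError("disease_context_terms must be non-empty")
        if not self.age_prefilter_patterns:
            raise ValueError("age_prefilter_patterns must be non-empty")
        for pat in self.disease_context_terms + self.age_prefilter_patterns:
            re.compile(pat)  # raises re.error on an invalid pattern

    @property
    def context_regexes(self):
        return [re.compile(p, re.IGNORECASE) for p in self.disease_context_terms]

    @property
    def age_regexes(self):
        return [re.compile(p, re.IGNORECASE) for p in self.age_prefilter_patterns]


@dataclass(frozen=True)
class DropRecord:
    note_id: str
    reason: str  # empty_text | note_type | no_context


# --------------------------------------------------------------------------
# Filtering


def filter_notes(
    notes: Sequence[ClinicalNote], config: PreprocessConfig = PreprocessConfig()
) -> Tuple[List[ClinicalNote], List[DropRecord]]:
    """Keep notes with text, an allowed note type and ≥1 disease-context hit.

    Pure function: every input note appears exactly once, either in the kept
    list or in the drop log, so ``|kept| + |dropped| == |input|``.
    """
    context_res = config.context_regexes
    excluded = {t.lower() for t in config.excluded_note_types}
    kept, dropped = [], []
    for note in notes:
        if not note.text.strip():
            dropped.append(DropRecord(note.note_id, "empty_text"))
        elif note.note_type.lower() in excluded:
            dropped.append(DropRecord(note.note_id, "note_type"))
        elif not any(r.search(note.text) for r in context_res):
            dropped.append(DropRecord(note.note_id, "no_context"))
        else:
            kept.append(note)
    return kept, dropped


def prefilter_age_notes(
    notes: Sequence[ClinicalNote], config: PreprocessConfig = PreprocessConfig()
) -> List[ClinicalNote]:
    """Keep notes matching at least one age-keyword pattern (case-insensitive)."""
    age_res = config.age_regexes
    return [n for n in notes if any(r.search(n.text) for r in age_res)]


# --------------------------------------------------------------------------
# Sentence segmentation

_BREAK_RE = re.compile(r"[.!?]+|\n+")


def _chunk_around(text: str, pos: int) -> str:
    """Whitespace-delimited chunk of `text` containing position `pos`."""
    start = pos
    while start > 0 and not text[start - 1].isspace():
        start -= 1
    end = pos
    while end < len(text) and not text[end].isspace():
        end += 1
    return text[start:end]


def segment_sentences(
    note: ClinicalNote, abbreviations: Iterable[str] = DEFAULT_ABBREVIATIONS
) -> List[Sentence]:
    """Split a note into sentences with exact character offsets.

    Breaks on ``.!?`` runs followed by whitespace/end-of-text and on
    newlines.  A period ending a token on the abbreviation list ("Dr.",
    "b.i.d.") or sitting inside a token ("2.5") never breaks.  Leading and
    trailing whitespace is trimmed from each span, so concatenating the
    sentence spans recovers every non-whitespace character of the note.
    """
    text = note.text
    if not text.strip():
        return []
    abbrev = {a.lower() for a in abbreviations}

    break_ends = []
    for m in _BREAK_RE.finditer(text):
        if m.group().startswith("\n"):
            break_ends.append(m.end())
            continue
        # terminator must end a whitespace-delimited token
        if m.end() < len(text) and not text[m.end()].isspace():
            continue
        if "." in m.group():
            chunk = _chunk_around(text, m.start()).lower()
            if chunk in abbrev:
                continue
            # also catch "Dr" followed by "." when chunk includes both, e.g. "(Dr.)"
            if chunk.strip("()[]\"'") in abbrev:
                continue
        break_ends.append(m.end())
    break_ends.append(len(text))

    sentences: List[Sentence] = []
    prev = 0
    for end in break_ends:
        if end <= prev:
            continue
        seg = text[prev:end]
        stripped = seg.strip()
        if stripped:
            start = prev + (len(seg) - len(seg.lstrip()))
            stop = start + len(stripped)
            sentences.append(
                Sentence(
                    note_id=note.note_id,
                    index=len(sentences),
                    char_start=start,
                    char_end=stop,
                    text=stripped,
                )
            )
        prev = end
    for s in sentences:
        s.validate_against(note)
    return sentences
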