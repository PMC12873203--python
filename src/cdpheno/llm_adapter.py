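"""Few-shot prompt construction, structured-output contract and backends.

A note-level labeler backend is any callable ``backend(prompt, config) ->
payload`` where ``payload`` is a flat dict with the keys of
:class:`StructuredOutput`.  The prompt concatenates (deterministically) the
condensed annotation guidelines, exactly three worked examples, the target
note, and the output-format instruction; with temperature 0 a live model is
as repeatable as the API allows.

Only the deterministic :func:`mock_backend` ships enabled: it is a test
double driven by the same bundled lexicon and negation triggers as the
rule-based labeler, but — deliberately — without anatomical-context
exclusion, so the two labelers genuinely disagree on confounder sentences
and the ensemble paths are exercised.  It makes no claim about how any real
LLM behaves.  A live adapter can be registered under its own backend id;
credentials belong in the environment, never in configs, and clinical text
sent to a remote API leaves the local system — weigh that before enabling
one.
"""

from __future__ import annotations

import datetime
import json
import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Dict, List, Sequence, Tuple

from . import behavior_rules
from .data_model import ClinicalNote, NoteLabel, behavior_binary
from .preprocess import segment_sentences

SCHEMA_VERSION = "1"

_TARGET_HEADER = "### Note to classify"
_OUTPUT_HEADER = "### Output format"


class PayloadError(ValueError):
    """Base class for structured-output violations."""


class MissingFieldError(PayloadError):
    pass


class UnknownFieldError(PayloadError):
    pass


class EnumValueError(PayloadError):
    pass


class MalformedPayloadError(PayloadError):
    pass


def load_default_guidelines() -> str:
    return (
        resources.files("cdpheno.assets").joinpath("guidelines.txt").read_text("utf-8")
    )


@dataclass(frozen=True)
class PromptSpec:
    guideline_text: str
    examples: Tuple[Tuple[str, dict], ...]  # (note text, expected payload) pairs
    target_text: str

    def __post_init__(self):
        if not self.guideline_text.strip():
            raise ValueError("guideline_text must be non-empty")
        if len(self.examples) != 3:
            raise ValueError(
                f"exactly 3 few-shot examples required, got {len(self.examples)}"
            )


@dataclass(frozen=True)
class LLMConfig:
    temperature: float = 0.0
    backend_id: str = "mock"
    schema_version: str = SCHEMA_VERSION
    seed: int = 0


#: backend contract: (prompt, config) → payload dict
Backend = Callable[[str, LLMConfig], Dict[str, str]]


def build_prompt(spec: PromptSpec, config: LLMConfig = LLMConfig()) -> str:
    """Deterministic prompt assembly; byte-identical for equal inputs + seed.

    Example order is fixed by the seed alone: examples are first put into a
    canonical order, then shuffled with ``random.Random(seed)``, so the
    caller's list order cannot leak into the prompt.
    """
    examples = sorted(spec.examples, key=lambda e: e[0])
    rng = random.Random(config.seed)
    rng.shuffle(examples)
    parts = ["### Annotation guidelines", spec.guideline_text.strip(), ""]
    for i, (text, payload) in enumerate(examples, start=1):
        parts += [
            f"### Example {i}",
            text.strip(),
            "Answer: " + json.dumps(payload, sort_keys=True),
            "",
        ]
    parts += [
        _TARGET_HEADER,
        spec.target_text.strip(),
        "",
        _OUTPUT_HEADER,
        'Respond with a JSON object {"behavior": "B1|B2|B3", '
        '"perianal": "yes|no"} and nothing else. '
        f"(schema v{config.schema_version})",
    ]
    return "\n".join(parts)


# --------------------------------------------------------------------------
# Structured output


@dataclass(frozen=True)
class StructuredOutput:
    behavior: str
    perianal: str
    behavior_binary: str

    @classmethod
    def from_payload(cls, payload: dict) -> "StructuredOutput":
        if not isinstance(payload, dict):
            raise MalformedPayloadError(
                f"payload must be a mapping, got {type(payload).__name__}"
            )
        allowed = {"behavior", "perianal", "behavior_binary"}
        unknown = set(payload) - allowed
        if unknown:
            raise UnknownFieldError(f"unknown payload keys: {sorted(unknown)}")
        for key in ("behavior", "perianal"):
            if key not in payload:
                raise MissingFieldError(f"payload missing required key {key!r}")
        behavior = payload["behavior"]
        if behavior not in ("B1", "B2", "B3"):
            raise EnumValueError(f"behavior must be B1|B2|B3, got {behavior!r}")
        perianal = payload["perianal"]
        if perianal not in ("yes", "no"):
            raise EnumValueError(f"perianal must be yes|no, got {perianal!r}")
        binary = behavior_binary(behavior)
        if "behavior_binary" in payload and payload["behavior_binary"] != binary:
            raise EnumValueError(
                f"behavior_binary {payload['behavior_binary']!r} inconsistent "
                f"with behavior {behavior!r}"
            )
        return cls(behavior=behavior, perianal=perianal, behavior_binary=binary)


def parse_output(payload: dict, note: ClinicalNote) -> NoteLabel:
    """Map a structured payload 1:1 onto a NoteLabel (source=llm).

    Invalid payloads raise a specific :class:`PayloadError` subclass —
    never a silent default label.
    """
    out = StructuredOutput.from_payload(payload)
    return NoteLabel(
        patient_id=note.patient_id,
        note_id=note.note_id,
        note_datetime=note.note_datetime,
        behavior=out.behavior,
        perianal=out.perianal == "yes",
        source="llm",
        evidence=(),
    )


# --------------------------------------------------------------------------
# Mock backend (deterministic test double)


def _extract_target_text(prompt: str) -> str:
    try:
        after = prompt.split(_TARGET_HEADER, 1)[1]
        return after.split(_OUTPUT_HEADER, 1)[0].strip()
    except IndexError:
        raise MalformedPayloadError("prompt lacks the target-note section") from None


def mock_backend(prompt: str, config: LLMConfig = LLMConfig()) -> Dict[str, str]:
    """Keyword heuristic over the target-note section of the prompt.

    Splits the target note into sentences, matches the bundled lexicon and
    applies the rule-based negation triggers — but performs no
    anatomical-context exclusion.  Same prompt → same payload, always.
    """
    text = _extract_target_text(prompt)
    lexicon = behavior_rules.load_default_lexicon()
    negation = behavior_rules.load_default_negation_config()
    # context exclusion disabled: empty non-target term set
    no_exclusion = behavior_rules.ContextExclusionConfig(
        non_target_context_terms=frozenset({"__none__"}), window_tokens=0
    )
    fake_note = ClinicalNote(
        patient_id="", note_id="__mock__",
        note_datetime=datetime.date(2000, 1, 1),
        note_type="progress note", text=text,
    )
    evidence = set()
    perianal = False
    for sent in segment_sentences(fake_note):
        label = behavior_rules.classify_sentence(
            sent, lexicon, negation, no_exclusion
        )
        evidence |= set(label.behavior_evidence)
        perianal = perianal or label.perianal
    behavior = "B3" if "B3" in evidence else ("B2" if "B2" in evidence else "B1")
    return {"behavior": behavior, "perianal": "yes" if perianal else "no"}


BACKENDS: Dict[str, Backend] = {"mock": mock_backend}


def label_notes(
    notes: Sequence[ClinicalNote],
    examples: Sequence[Tuple[str, dict]],
    guidelines: str = None,
    config: LLMConfig = LLMConfig(),
    backend: Backend = None,
) -> List[NoteLabel]:
    """Run the prompt → backend → parse loop over a corpus."""
    guidelines = guidelines if guidelines is not None else load_default_guidelines()
    backend = backend if backend is not None else BACKENDS[config.backend_id]
    labels = []
    for note in notes:
        spec = PromptSpec(
            guideline_text=guidelines,
            examples=tuple(examples),
            target_text=note.text,
        )
        payload = backend(build_prompt(spec, config), config)
        labels.append(parse_output(payload, note))
    return labels


#: three development-set style worked examples used as the default few-shot set
DEFAULT_EXAMPLES: Tuple[Tuple[str, dict], ...] = (
    (
        "Patient with Crohn's disease seen in follow-up. Imaging demonstrates "
        "an ileal stricture. No perianal disease on exam.",
        {"behavior": "B2", "perianal": "no"},
    ),
    (
        "Crohn's disease. Examination reveals a perianal abscess. "
        "Seton in place.",
        {"behavior": "B3", "perianal": "yes"},
    ),
    (
        "Follow-up for Crohn's ileocolitis. No evidence of stricture or "
        "fistula. Continue current therapy.",
        {"behavior": "B1", "perianal": "no"},
    ),
)
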