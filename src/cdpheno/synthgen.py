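"""Seeded generator of fictional clinical corpora with gold labels.

The real study corpus is protected health information and cannot ship, so
this module emulates its statistical structure: per patient a latent truth
(behavior flags, perianal status, birth year, diagnosis age) is sampled,
then notes are rendered from templates organized by difficulty tier —

* tier 1: unambiguous sentences built only from the bundled lexicon;
* negated: the same complications inside negation scopes;
* confounder: the same complication words in non-intestinal contexts
  ("carotid stenosis"), which a correct extractor must ignore;
* out-of-lexicon: complications paraphrased with words outside the bundled
  terminology — known-hard cases the rules are expected to miss.

Age-at-diagnosis statements are rendered in the three surface forms at a
configurable mix, by default 60% year of diagnosis, 23% direct age, 10%
duration (the remainder of notes carries no age statement).  Gold labels at
sentence, note and patient level are exact by construction: they record
what the rendered text asserts, so a positive patient whose notes happen to
never mention the complication is gold-negative, exactly as chart review of
those notes would conclude.

Same seed → byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .data_model import (
    ClinicalNote,
    Demographics,
    NoteLabel,
    PatientLabel,
    SentenceLabel,
    max_severity,
    write_demographics,
    write_labels,
    write_notes,
)
from .aggregate import montreal_age_category


class GeneratorConfigError(ValueError):
    """Config is internally infeasible (checked before any sampling)."""


@dataclass(frozen=True)
class GeneratorConfig:
    n_patients: int = 100
    notes_per_patient: Tuple[int, int] = (8, 12)
    #: patient-level complication prevalences
    prevalence_b2: float = 0.30
    prevalence_b3: float = 0.20
    prevalence_perianal: float = 0.15
    #: chance a positive patient's note mentions each of their complications
    mention_probability: float = 0.35
    #: fraction of rendered complication mentions written as negated
    negated_mention_rate: float = 0.10
    #: chance a note of a negative patient carries a negated mention
    negative_negated_rate: float = 0.05
    #: chance a note carries a non-intestinal confounder sentence
    confounder_rate: float = 0.05
    #: chance a positive patient's note states a complication in words
    #: outside the bundled lexicon (known-hard case)
    ambiguity_rate: float = 0.0
    #: P(diagnosis_year), P(direct_age), P(duration) per note; remainder = none
    age_mix: Tuple[float, float, float] = (0.60, 0.23, 0.10)
    #: chance a note is an excluded administrative type (no clinical content)
    excluded_note_type_rate: float = 0.05
    #: chance a note has no Crohn's context at all (dropped by preprocess)
    no_context_note_rate: float = 0.03
    enrollment_year: int = 2020
    #: note years relative to enrollment, inclusive
    note_year_window: Tuple[int, int] = (-4, 0)
    seed: int = 0

    def __post_init__(self):
        probs = (
            self.prevalence_b2,
            self.prevalence_b3,
            self.prevalence_perianal,
            self.mention_probability,
            self.negated_mention_rate,
            self.negative_negated_rate,
            self.confounder_rate,
            self.ambiguity_rate,
            self.excluded_note_type_rate,
            self.no_context_note_rate,
        ) + self.age_mix
        if any(not (0 <= p <= 1) for p in probs):
            raise GeneratorConfigError("all probabilities must lie in [0, 1]")
        if sum(self.age_mix) > 1 + 1e-9:
            raise GeneratorConfigError("age_mix must sum to <= 1")
        if self.n_patients < 1:
            raise GeneratorConfigError("n_patients must be >= 1")
        lo, hi = self.notes_per_patient
        if not (1 <= lo <= hi):
            raise GeneratorConfigError("notes_per_patient must satisfy 1 <= lo <= hi")
        if self.note_year_window[0] > self.note_year_window[1]:
            raise GeneratorConfigError("note_year_window must be (lo, hi) with lo <= hi")
        positives = max(
            self.prevalence_b2, self.prevalence_b3, self.prevalence_perianal
        )
        if positives > 0 and self.mention_probability == 0:
            raise GeneratorConfigError(
                "positive prevalence with zero mention probability can never "
                "render any complication evidence"
            )


# --------------------------------------------------------------------------
# Templates.  Each complication template carries its gold evidence:
# (text, behavior classes asserted, perianal asserted).

CONTEXT_SENTENCES = (
    "Patient with Crohn's disease seen in clinic for routine follow-up.",
    "Follow-up visit for Crohn's ileocolitis.",
    "The patient has an established diagnosis of Crohn's disease.",
    "Crohn's disease, currently maintained on biologic therapy.",
)

FILLER_SENTENCES = (
    "Vital signs are stable.",
    "He reports intermittent abdominal pain.",
    "Labs were reviewed and are unremarkable.",
    "Continue current medications and return in 3 months.",
    "Colonoscopy scheduled for next month.",
    "Denies fever or chills.",
)

Template = Tuple[str, frozenset, bool]  # text, behavior evidence, perianal


def _t(text: str, behaviors: Sequence[str] = (), perianal: bool = False) -> Template:
    return (text, frozenset(behaviors), perianal)


B2_ASSERTED = (
    _t("Imaging demonstrates an ileal stricture.", ("B2",)),
    _t("There is a stricture in the terminal ileum.", ("B2",)),
    _t("CT shows luminal narrowing of the distal ileum.", ("B2",)),
    _t("Anastomotic stricture noted on endoscopy.", ("B2",)),
    _t("Findings are consistent with small bowel obstruction.", ("B2",)),
)
B2_NEGATED = (
    _t("No stricture is seen on imaging."),
    _t("No evidence of stricture or obstruction."),
    _t("There is no evidence of luminal narrowing."),
)
B3_ASSERTED = (
    _t("MRI reveals an enterocutaneous fistula.", ("B3",)),
    _t("There is a pelvic abscess measuring 3 cm.", ("B3",)),
    _t("Known RVF.", ("B3",)),
    _t("An intra-abdominal abscess is present.", ("B3",)),
    _t("CT demonstrates a bowel perforation.", ("B3",)),
)
B3_NEGATED = (
    _t("No fistula or abscess is identified."),
    _t("No evidence of fistula formation."),
    _t("Abscess was ruled out."),
    _t("Denies any fistula drainage."),
)
PERIANAL_ASSERTED = (
    _t("Perianal fistula with seton in place.", ("B3",), True),
    _t("Examination reveals a perianal abscess.", ("B3",), True),
    _t("Anal fissure noted on exam.", (), True),
    _t("Perianal disease with prominent skin tags.", (), True),
)
PERIANAL_NEGATED = (
    _t("No perianal fistula or abscess on exam."),
    _t("No perianal disease on exam."),
)
CONFOUNDER_SENTENCES = (
    _t("History of carotid stenosis followed by vascular surgery."),
    _t("Severe aortic stenosis seen on echocardiogram."),
    _t("Spinal stenosis contributes to chronic back pain."),
    _t("Known coronary stenosis status post stent."),
)
#: complications stated in words outside the bundled lexicon (rules miss these)
OUT_OF_LEXICON = {
    "B2": _t("The distal ileal lumen appears severely compromised.", ("B2",)),
    "B3": _t(
        "There is an abnormal communication between adjacent bowel loops.", ("B3",)
    ),
    "perianal": _t(
        "Painful induration adjacent to the anal verge with drainage.", (), True
    ),
}

EXCLUDED_TYPE_TEXT = "Patient called regarding prescription refill for Crohn's disease."
NO_CONTEXT_TEXT = "Patient seen for ankle sprain. Advised rest and ice."

AGE_TEMPLATES = {
    "diagnosis_year": (
        "Diagnosed with Crohn's disease in {year}.",
        "Crohn's disease since {year}.",
    ),
    "direct_age": (
        "Diagnosed with Crohn's disease at age {age}.",
        "The patient was diagnosed at age {age} with Crohn's disease.",
    ),
    "duration_years": (
        "Crohn's disease for {n} years.",
        "{n}-year history of Crohn's disease.",
    ),
    "duration_months": ("{n}-month history of Crohn's disease.",),
}


# --------------------------------------------------------------------------
# Latent truth and corpus containers


@dataclass(frozen=True)
class LatentPatient:
    patient_id: str
    birth_year: int
    diagnosis_age: int
    diagnosis_year: int
    b2: bool
    b3: bool
    perianal: bool


@dataclass
class Corpus:
    config: GeneratorConfig
    notes: List[ClinicalNote]
    demographics: List[Demographics]
    gold_sentence: List[SentenceLabel]
    gold_note: List[NoteLabel]
    gold_patient: List[PatientLabel]
    #: note_id → stated age at diagnosis (None when the note states none)
    gold_note_ages: Dict[str, Optional[float]]
    latent: List[LatentPatient]
    #: note_id → age surface form actually rendered (None when none)
    age_forms: Dict[str, Optional[str]]

    @property
    def manifest(self) -> dict:
        return {
            "generator": "cdpheno.synthgen",
            "config": dataclasses.asdict(self.config),
            "n_patients": len(self.latent),
            "n_notes": len(self.notes),
            "latent": [dataclasses.asdict(p) for p in self.latent],
        }


# --------------------------------------------------------------------------
# Generation


def _sample_latent(rng: random.Random, config: GeneratorConfig, i: int) -> LatentPatient:
    pid = f"p{i:04d}"
    birth_year = rng.randint(1940, 1990)
    earliest_note_year = config.enrollment_year + config.note_year_window[0]
    max_age = min(60, earliest_note_year - 1 - birth_year)
    age = rng.randint(10, max(10, max_age))
    return LatentPatient(
        patient_id=pid,
        birth_year=birth_year,
        diagnosis_age=age,
        diagnosis_year=birth_year + age,
        b2=rng.random() < config.prevalence_b2,
        b3=rng.random() < config.prevalence_b3,
        perianal=rng.random() < config.prevalence_perianal,
    )


def _age_sentence(
    rng: random.Random, config: GeneratorConfig, patient: LatentPatient, note_year: int
) -> Tuple[Optional[str], Optional[str]]:
    """(sentence text, surface form) or (None, None) for no age statement."""
    r = rng.random()
    p_year, p_direct, p_dur = config.age_mix
    if r < p_year:
        kind = "diagnosis_year"
    elif r < p_year + p_direct:
        kind = "direct_age"
    elif r < p_year + p_direct + p_dur:
        kind = "duration"
    else:
        return None, None
    duration_years = note_year - patient.diagnosis_year
    if kind == "duration" and duration_years < 1:
        kind = "diagnosis_year"  # a future-dated duration is not writable
    if kind == "diagnosis_year":
        tpl = rng.choice(AGE_TEMPLATES["diagnosis_year"])
        return tpl.format(year=patient.diagnosis_year), kind
    if kind == "direct_age":
        tpl = rng.choice(AGE_TEMPLATES["direct_age"])
        return tpl.format(age=patient.diagnosis_age), kind
    if duration_years <= 2 and rng.random() < 0.5:
        tpl = rng.choice(AGE_TEMPLATES["duration_months"])
        return tpl.format(n=duration_years * 12), "duration"
    tpl = rng.choice(AGE_TEMPLATES["duration_years"])
    return tpl.format(n=duration_years), "duration"


def _render_note(
    rng: random.Random,
    config: GeneratorConfig,
    patient: LatentPatient,
    note_index: int,
) -> Tuple[ClinicalNote, List[Template], Optional[float], Optional[str]]:
    """One note plus its per-sentence gold and stated age."""
    note_id = f"n-{patient.patient_id}-{note_index:03d}"
    year = config.enrollment_year + rng.randint(*config.note_year_window)
    date = datetime.date(year, rng.randint(1, 12), rng.randint(1, 28))

    roll = rng.random()
    if roll < config.excluded_note_type_rate:
        note = ClinicalNote(
            patient.patient_id, note_id, date, "telephone encounter",
            EXCLUDED_TYPE_TEXT,
        )
        return note, [_t(EXCLUDED_TYPE_TEXT)], None, None
    if roll < config.excluded_note_type_rate + config.no_context_note_rate:
        note = ClinicalNote(
            patient.patient_id, note_id, date, "progress note", NO_CONTEXT_TEXT
        )
        return note, [_t("Patient seen for ankle sprain."), _t("Advised rest and ice.")], None, None

    sentences: List[Template] = [_t(rng.choice(CONTEXT_SENTENCES))]
    body: List[Template] = []

    for positive, asserted_pool, negated_pool in (
        (patient.b2, B2_ASSERTED, B2_NEGATED),
        (patient.b3, B3_ASSERTED, B3_NEGATED),
        (patient.perianal, PERIANAL_ASSERTED, PERIANAL_NEGATED),
    ):
        if positive:
            if rng.random() < config.mention_probability:
                if rng.random() < config.negated_mention_rate:
                    body.append(rng.choice(negated_pool))
                else:
                    body.append(rng.choice(asserted_pool))
        elif rng.random() < config.negative_negated_rate:
            body.append(rng.choice(negated_pool))

    if rng.random() < config.confounder_rate:
        body.append(rng.choice(CONFOUNDER_SENTENCES))

    if config.ambiguity_rate > 0 and rng.random() < config.ambiguity_rate:
        cats = [
            c
            for c, flag in (
                ("B2", patient.b2), ("B3", patient.b3), ("perianal", patient.perianal)
            )
            if flag
        ]
        if cats:
            body.append(OUT_OF_LEXICON[rng.choice(cats)])

    age_text, age_form = _age_sentence(rng, config, patient, year)
    stated_age: Optional[float] = None
    if age_text is not None:
        body.append(_t(age_text))
        stated_age = float(patient.diagnosis_age)

    for _ in range(rng.randint(1, 3)):
        body.append(_t(rng.choice(FILLER_SENTENCES)))

    rng.shuffle(body)
    sentences.extend(body)
    text = " ".join(s[0] for s in sentences)
    note = ClinicalNote(patient.patient_id, note_id, date, "progress note", text)
    return note, sentences, stated_age, age_form


def generate_corpus(
    config: GeneratorConfig = GeneratorConfig(),
    out_dir: Optional[Path] = None,
) -> Corpus:
    """Generate a corpus; optionally write all artifact files to `out_dir`.

    Files written: notes.jsonl, demographics.csv, gold_sentence.csv,
    gold_note.csv, gold_patient.csv, gold_note_ages.csv, manifest.json.
    """
    rng = random.Random(config.seed)
    notes: List[ClinicalNote] = []
    demographics: List[Demographics] = []
    gold_sentence: List[SentenceLabel] = []
    gold_note: List[NoteLabel] = []
    gold_patient: List[PatientLabel] = []
    gold_note_ages: Dict[str, Optional[float]] = {}
    age_forms: Dict[str, Optional[str]] = {}
    latent: List[LatentPatient] = []

    for i in range(config.n_patients):
        patient = _sample_latent(rng, config, i)
        latent.append(patient)
        demographics.append(
            Demographics(
                patient_id=patient.patient_id,
                birth_year=patient.birth_year,
                enrollment_year=config.enrollment_year,
            )
        )
        patient_notes: List[NoteLabel] = []
        patient_ages: List[float] = []
        for j in range(rng.randint(*config.notes_per_patient)):
            note, sent_templates, stated_age, age_form = _render_note(
                rng, config, patient, j
            )
            notes.append(note)
            gold_note_ages[note.note_id] = stated_age
            age_forms[note.note_id] = age_form
            if stated_age is not None:
                patient_ages.append(stated_age)
            behaviors: List[str] = []
            perianal = False
            for idx, (text, evidence, peri) in enumerate(sent_templates):
                gold_sentence.append(
                    SentenceLabel(
                        note_id=note.note_id,
                        sentence_index=idx,
                        behavior_evidence=evidence,
                        perianal=peri,
                    )
                )
                behaviors.extend(evidence)
                perianal = perianal or peri
            nl = NoteLabel(
                patient_id=patient.patient_id,
                note_id=note.note_id,
                note_datetime=note.note_datetime,
                behavior=max_severity(behaviors),
                perianal=perianal,
                source="gold",
            )
            gold_note.append(nl)
            patient_notes.append(nl)
        age = min(patient_ages) if patient_ages else None
        gold_patient.append(
            PatientLabel(
                patient_id=patient.patient_id,
                behavior=max_severity(n.behavior for n in patient_notes),
                perianal=any(n.perianal for n in patient_notes),
                source="gold",
                age_at_diagnosis=age,
                montreal_age=None if age is None else montreal_age_category(age),
            )
        )

    corpus = Corpus(
        config=config,
        notes=notes,
        demographics=demographics,
        gold_sentence=gold_sentence,
        gold_note=gold_note,
        gold_patient=gold_patient,
        gold_note_ages=gold_note_ages,
        latent=latent,
        age_forms=age_forms,
    )
    if out_dir is not None:
        write_corpus(corpus, Path(out_dir))
    return corpus


def write_corpus(corpus: Corpus, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_notes(corpus.notes, out_dir / "notes.jsonl")
    write_demographics(corpus.demographics, out_dir / "demographics.csv")
    write_labels(corpus.gold_sentence, out_dir / "gold_sentence.csv", "sentence")
    write_labels(corpus.gold_note, out_dir / "gold_note.csv", "note")
    write_labels(corpus.gold_patient, out_dir / "gold_patient.csv", "patient")
    with open(out_dir / "gold_note_ages.csv", "w", encoding="utf-8", newline="") as fh:
        fh.write("note_id,age_at_diagnosis,age_form\n")
        for note in corpus.notes:
            age = corpus.gold_note_ages[note.note_id]
            form = corpus.age_forms[note.note_id]
            fh.write(
                f"{note.note_id},{'' if age is None else repr(age)},{form or ''}\n"
            )
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(corpus.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
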