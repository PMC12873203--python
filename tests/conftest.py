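import dataclasses
import datetime

import pytest

from cdpheno.data_model import ClinicalNote, Sentence
from cdpheno.behavior_rules import (
    load_default_lexicon,
    load_default_negation_config,
)
from cdpheno.synthgen import GeneratorConfig, generate_corpus


def make_note(text, note_id="n1", patient_id="p1", note_type="progress note",
              date=datetime.date(2015, 3, 2)):
    return ClinicalNote(
        patient_id=patient_id, note_id=note_id, note_datetime=date,
        note_type=note_type, text=text,
    )


def make_sentence(text, note_id="n1", index=0):
    return Sentence(
        note_id=note_id, index=index, char_start=0, char_end=len(text), text=text
    )


@pytest.fixture(scope="session")
def lexicon():
    return load_default_lexicon()


@pytest.fixture(scope="session")
def negation():
    return load_default_negation_config()


@pytest.fixture(scope="session")
def tier1_config():
    """Unambiguous lexicon-only study conditions: no confounders, no
    out-of-lexicon phrasing; everything else at the shipped defaults."""
    return GeneratorConfig(
        n_patients=100, seed=11, confounder_rate=0.0, ambiguity_rate=0.0
    )


@pytest.fixture(scope="session")
def tier1_corpus(tier1_config):
    return generate_corpus(tier1_config)


@pytest.fixture(scope="session")
def default_corpus():
    """Shipped default conditions (includes confounder sentences)."""
    return generate_corpus(GeneratorConfig(n_patients=60, seed=5))
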