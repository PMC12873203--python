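import pytest

from cdpheno.age_rules import (
    AgePatternSet,
    AgeRangeError,
    AgeResolutionError,
    extract_age_evidence,
    resolve_age,
    resolve_note_age,
)
from cdpheno.data_model import AgeEvidence, ReferenceContext
from conftest import make_sentence

PATTERNS = AgePatternSet()


def _ev(kind, value, unit=None, note_id="n1"):
    return AgeEvidence(
        note_id=note_id, sentence_index=0, kind=kind, raw_value=value, raw_unit=unit
    )


class TestExtractAgeEvidence:
    @pytest.mark.parametrize(
        "text,kind,value,unit",
        [
            ("diagnosed with Crohn's at age 25", "direct_age", 25, None),
            ("Crohn's disease since 2005", "diagnosis_year", 2005, None),
            ("18-month history of Crohn's disease", "duration", 18, "months"),
            ("Crohn's disease for 12 years", "duration", 12, "years"),
            ("diagnosed with CD in 1998", "diagnosis_year", 1998, None),
            ("The patient was diagnosed at age 31 with Crohn's disease.",
             "direct_age", 31, None),
        ],
    )
    def test_three_surface_forms(self, text, kind, value, unit):
        (ev,) = extract_age_evidence(make_sentence(text), PATTERNS)
        assert (ev.kind, ev.raw_value, ev.raw_unit) == (kind, value, unit)

    def test_no_temporal_language_no_evidence(self):
        assert extract_age_evidence(make_sentence("Crohn's disease, stable."), PATTERNS) == []

    def test_vague_decade_out_of_scope(self):
        sent = make_sentence("diagnosed in his 20s")
        assert extract_age_evidence(sent, PATTERNS) == []

    def test_implausible_year_discarded(self):
        sent = make_sentence("Crohn's disease since 2019")
        assert extract_age_evidence(sent, PATTERNS, note_year=2015) == []

    def test_future_year_relative_to_note_discarded_but_valid_kept(self):
        sent = make_sentence("Crohn's disease since 2010")
        (ev,) = extract_age_evidence(sent, PATTERNS, note_year=2015)
        assert ev.raw_value == 2010


class TestResolveAge:
    def test_direct_age_identity(self):
        assert resolve_age(_ev("direct_age", 25), ReferenceContext(2015)) == 25.0

    def test_diagnosis_year_via_age_at_reference(self):
        ctx = ReferenceContext(reference_year=2015, age_at_reference=35)
        assert resolve_age(_ev("diagnosis_year", 2005), ctx) == 25.0

    def test_diagnosis_year_via_birth_year(self):
        ctx = ReferenceContext(reference_year=2015, birth_year=1980)
        assert resolve_age(_ev("diagnosis_year", 2005), ctx) == 25.0

    def test_routes_agree_when_context_exactly_consistent(self):
        ctx = ReferenceContext(reference_year=2015, age_at_reference=35, birth_year=1980)
        via_age = resolve_age(_ev("diagnosis_year", 2002), ctx)
        via_birth = 2002 - 1980
        assert via_age == via_birth

    def test_duration_months_converted_to_years(self):
        ctx = ReferenceContext(reference_year=2015, age_at_reference=30)
        assert resolve_age(_ev("duration", 18, "months"), ctx) == pytest.approx(28.5)

    def test_duration_years(self):
        ctx = ReferenceContext(reference_year=2015, age_at_reference=30)
        assert resolve_age(_ev("duration", 4, "years"), ctx) == 26.0

    def test_missing_context_names_field(self):
        with pytest.raises(AgeResolutionError) as err:
            resolve_age(_ev("duration", 4, "years"), ReferenceContext(2015))
        assert err.value.field == "age_at_reference"

    def test_out_of_range_result_rejected(self):
        ctx = ReferenceContext(reference_year=2015, age_at_reference=30)
        with pytest.raises(AgeRangeError):
            resolve_age(_ev("duration", 40, "years"), ctx)

    def test_inconsistent_context_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            ReferenceContext(reference_year=2015, age_at_reference=20, birth_year=1980)


class TestResolveNoteAge:
    ctx = ReferenceContext(reference_year=2015, age_at_reference=40)

    def test_concordant_values(self):
        res = resolve_note_age([_ev("direct_age", 25), _ev("direct_age", 25)], self.ctx)
        assert res.age_at_diagnosis == 25.0 and not res.discordant

    def test_discordant_values_take_minimum_and_flag(self):
        # oracle: min + pairwise-difference check
        res = resolve_note_age([_ev("direct_age", 25), _ev("direct_age", 31)], self.ctx)
        assert res.age_at_diagnosis == 25.0 and res.discordant

    def test_within_one_year_not_discordant(self):
        res = resolve_note_age([_ev("direct_age", 25), _ev("direct_age", 26)], self.ctx)
        assert not res.discordant

    def test_empty_evidence_gives_null(self):
        assert resolve_note_age([], self.ctx) is None

    def test_unresolvable_evidence_skipped_not_fatal(self):
        res = resolve_note_age(
            [_ev("duration", 4, "years"), _ev("direct_age", 30)],
            ReferenceContext(2015),  # no age_at_reference: duration unresolvable
        )
        assert res.age_at_diagnosis == 30.0

    def test_mixed_notes_rejected(self):
        with pytest.raises(ValueError, match="multiple notes"):
            resolve_note_age(
                [_ev("direct_age", 25, note_id="n1"), _ev("direct_age", 25, note_id="n2")],
                self.ctx,
            )


class TestCrossFormatConsistency:
    def test_three_forms_agree_within_margin_on_corpus(self, tier1_corpus):
        """All rendered surface forms resolve to within 1 year of the latent
        diagnosis age — the year-granularity margin absorbs the rest."""
        from cdpheno.preprocess import segment_sentences

        latent = {p.patient_id: p for p in tier1_corpus.latent}
        checked = 0
        for note in tier1_corpus.notes:
            gold = tier1_corpus.gold_note_ages[note.note_id]
            if gold is None:
                continue
            patient = latent[note.patient_id]
            ctx = ReferenceContext(
                reference_year=note.note_year,
                age_at_reference=float(note.note_year - patient.birth_year),
                birth_year=patient.birth_year,
            )
            evidence = []
            for sent in segment_sentences(note):
                evidence.extend(extract_age_evidence(sent, PATTERNS, note.note_year))
            res = resolve_note_age(evidence, ctx)
            assert res is not None, f"no age extracted from {note.note_id}"
            assert abs(res.age_at_diagnosis - patient.diagnosis_age) <= 1.0
            checked += 1
        assert checked > 100  # the mix guarantees most notes state an age
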