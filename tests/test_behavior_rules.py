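import pytest

from cdpheno.behavior_rules import (
    ContextExclusionConfig,
    analyze_sentence,
    apply_context_exclusion,
    classify_assertion,
    classify_sentence,
    expand_abbreviations,
    match_mentions,
)
from conftest import make_sentence


class TestExpandAbbreviations:
    def test_known_short_form_annotated(self, lexicon):
        (exp,) = expand_abbreviations(make_sentence("known RVF"), lexicon)
        assert exp.expansion == "rectovaginal fistula"
        assert (exp.char_start, exp.char_end) == (6, 9)

    def test_no_short_form_no_annotation(self, lexicon):
        assert expand_abbreviations(make_sentence("stable disease"), lexicon) == []

    def test_non_phenotype_expansion_yields_no_mention(self, lexicon):
        sent = make_sentence("MRI performed today")
        assert len(expand_abbreviations(sent, lexicon)) == 1
        assert match_mentions(sent, lexicon) == []


class TestMatchMentions:
    def test_single_b2_term(self, lexicon):
        (m,) = match_mentions(make_sentence("anastomotic stricture noted"), lexicon)
        assert m.category == "B2"
        assert m.matched_text == "anastomotic stricture"

    def test_two_b3_mentions(self, lexicon):
        mentions = match_mentions(
            make_sentence("enterocutaneous fistula with abscess"), lexicon
        )
        assert [m.category for m in mentions] == ["B3", "B3"]

    def test_no_lexicon_term_no_mentions(self, lexicon):
        assert match_mentions(make_sentence("patient denies pain"), lexicon) == []

    def test_abbreviation_route_mention_over_short_form_span(self, lexicon):
        sent = make_sentence("Known RVF.")
        (m,) = match_mentions(sent, lexicon)
        assert m.category == "B3"
        assert m.matched_text == "RVF"

    def test_overlapping_same_category_merged_to_widest(self, lexicon):
        (m,) = match_mentions(make_sentence("small bowel obstruction seen"), lexicon)
        assert m.matched_text == "small bowel obstruction"

    def test_token_boundaries_respected(self, lexicon):
        # "restriction" contains the letters of "stricture"-like substrings;
        # token matching must not fire inside other words
        assert match_mentions(make_sentence("diet restriction advised"), lexicon) == []

    def test_monotonicity_removing_entry_never_adds_mentions(self, lexicon):
        sent = make_sentence("ileal stricture with fistula")
        before = {(m.char_start, m.char_end, m.category) for m in match_mentions(sent, lexicon)}
        after = {
            (m.char_start, m.char_end, m.category)
            for m in match_mentions(sent, lexicon.without_pattern("stricture"))
        }
        assert after <= before

    def test_determinism(self, lexicon):
        sent = make_sentence("perianal fistula with abscess and stricture")
        assert match_mentions(sent, lexicon) == match_mentions(sent, lexicon)


class TestClassifyAssertion:
    def _mention(self, sent, text, lexicon):
        return next(m for m in match_mentions(sent, lexicon) if text in m.matched_text)

    def test_canonical_negation(self, lexicon, negation):
        sent = make_sentence("no evidence of fistula")
        m = self._mention(sent, "fistula", lexicon)
        assert classify_assertion(sent, m, negation) == "negated"

    def test_scope_terminator_shields_earlier_mention(self, lexicon, negation):
        # oracle: hand trace — "no" follows "fistula", so the pre-trigger is
        # out of scope for it; "abscess" sits inside the trigger scope
        sent = make_sentence("fistula present, but no abscess")
        fistula = self._mention(sent, "fistula", lexicon)
        abscess = self._mention(sent, "abscess", lexicon)
        assert classify_assertion(sent, fistula, negation) == "asserted"
        assert classify_assertion(sent, abscess, negation) == "negated"

    def test_plain_finding_asserted(self, lexicon, negation):
        sent = make_sentence("perianal abscess drained")
        m = self._mention(sent, "perianal abscess", lexicon)
        assert classify_assertion(sent, m, negation) == "asserted"

    def test_post_trigger(self, lexicon, negation):
        sent = make_sentence("abscess was ruled out")
        m = self._mention(sent, "abscess", lexicon)
        assert classify_assertion(sent, m, negation) == "negated"

    def test_trigger_beyond_scope_window(self, lexicon, negation):
        sent = make_sentence(
            "no improvement of the chronic symptoms despite escalation of therapy, "
            "with imaging showing a stricture"
        )
        m = self._mention(sent, "stricture", lexicon)
        assert classify_assertion(sent, m, negation) == "asserted"

    def test_historical_mention_counts_as_asserted(self, lexicon, negation):
        sent = make_sentence("history of fistula, resolved")
        m = self._mention(sent, "fistula", lexicon)
        assert classify_assertion(sent, m, negation) == "asserted"


class TestContextExclusion:
    config = ContextExclusionConfig()

    def _mention(self, sent, lexicon):
        return match_mentions(sent, lexicon)[0]

    def test_carotid_stenosis_excluded(self, lexicon):
        sent = make_sentence("known carotid stenosis")
        assert apply_context_exclusion(sent, self._mention(sent, lexicon), self.config)

    def test_ileal_stricture_not_excluded(self, lexicon):
        sent = make_sentence("ileal stricture")
        assert not apply_context_exclusion(sent, self._mention(sent, lexicon), self.config)

    def test_window_contract(self, lexicon):
        filler = "was documented many years ago and furthermore on review of systems " \
                 "today there is new concern for a significant"
        sent = make_sentence(f"carotid disease {filler} stenosis")
        m = self._mention(sent, lexicon)
        assert not apply_context_exclusion(sent, m, ContextExclusionConfig(window_tokens=6))
        assert apply_context_exclusion(sent, m, ContextExclusionConfig(window_tokens=50))

    def test_perianal_mentions_never_excluded(self, lexicon):
        sent = make_sentence("carotid surgery; perianal abscess noted")
        m = next(m for m in match_mentions(sent, lexicon) if m.category == "perianal")
        assert not apply_context_exclusion(sent, m, self.config)


class TestClassifySentence:
    def test_perianal_fistula_contributes_b3_and_perianal(self, lexicon, negation):
        # oracle: compose matching, assertion, exclusion by hand
        label = classify_sentence(
            make_sentence("Perianal fistula with seton in place."), lexicon, negation
        )
        assert label.behavior_evidence == frozenset({"B3"})
        assert label.perianal is True

    def test_negated_sentence_contributes_nothing(self, lexicon, negation):
        label = classify_sentence(
            make_sentence("No stricture or fistula on imaging."), lexicon, negation
        )
        assert label.behavior_evidence == frozenset()
        assert label.perianal is False

    def test_neutral_sentence_empty_label(self, lexicon, negation):
        label = classify_sentence(make_sentence("Follow-up in 3 months."), lexicon, negation)
        assert label.behavior_evidence == frozenset() and not label.perianal

    def test_perianal_only_term_gives_no_behavior(self, lexicon, negation):
        label = classify_sentence(
            make_sentence("Anal fissure noted on exam."), lexicon, negation
        )
        assert label.behavior_evidence == frozenset()
        assert label.perianal is True

    def test_pluggable_assertion_classifier(self, lexicon, negation):
        """A stub classifier with the documented signature slots in without
        any other change; negating everything suppresses all evidence."""
        negate_all = lambda sentence, mention, config: "negated"
        label = classify_sentence(
            make_sentence("Large perianal abscess with fistula."),
            lexicon, negation, assertion_classifier=negate_all,
        )
        assert label.behavior_evidence == frozenset() and not label.perianal

        assert_all = lambda sentence, mention, config: "asserted"
        label = classify_sentence(
            make_sentence("No fistula."), lexicon, negation,
            assertion_classifier=assert_all,
        )
        assert label.behavior_evidence == frozenset({"B3"})

    def test_mentions_carry_assertion_and_exclusion(self, lexicon, negation):
        mentions = analyze_sentence(
            make_sentence("Known carotid stenosis; no fistula."), lexicon, negation
        )
        by_cat = {m.category: m for m in mentions}
        assert by_cat["B2"].excluded_by_context is True
        assert by_cat["B3"].assertion == "negated"
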