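"""Per-sentence detection of stricturing (B2), penetrating (B3) and perianal
disease evidence.

The behavioral categorizer runs four stages over each sentence:

1. abbreviation expansion (annotations over the original text, offsets kept);
2. dual-route mention matching — direct surface-string patterns plus a
   bundled concept dictionary with synonym lists, both token-boundary aware
   and case-insensitive, overlapping same-category matches merged;
3. assertion classification — a NegEx/ConText-style trigger/scope rule, with
   a pluggable classifier interface so a statistical assertion model can be
   dropped in without touching any other stage;
4. anatomical-context exclusion — B2/B3 mentions near a non-intestinal
   context term ("carotid stenosis", "spinal stenosis", ...) are discarded.

Montreal behavior is cumulative over disease history, so historical mentions
("history of fistula, resolved") count as asserted: only explicit negation
flips a mention.  Perianal complications that are themselves penetrating
lesions (perianal fistula/abscess) also contribute B3 evidence by default;
set ``perianal_implies_behavior=False`` on the lexicon to disable.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable, List, Optional, Sequence, Tuple

from .data_model import PhenotypeMention, Sentence, SentenceLabel

# --------------------------------------------------------------------------
# Tokenizer contract: split on non-alphanumerics, keep hyphenated terms and
# internal apostrophes whole ("intra-abdominal", "Crohn's").

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:['\-][A-Za-z0-9]+)*")


def tokenize(text: str) -> List[Tuple[str, int, int]]:
    """Lowercased tokens with (start, end) character spans."""
    return [(m.group().lower(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def _term_tokens(term: str) -> Tuple[str, ...]:
    return tuple(t for t, _, _ in tokenize(term))


# --------------------------------------------------------------------------
# Lexicon


@dataclass(frozen=True)
class LexiconEntry:
    pattern: str
    category: str  # B2 | B3 | perianal
    route: str  # string | concept
    concept_id: Optional[str] = None
    implies_behavior: Optional[str] = None


@dataclass(frozen=True)
class PhenotypeLexicon:
    entries: Tuple[LexiconEntry, ...]
    abbreviation_map: Tuple[Tuple[str, str], ...] = ()
    perianal_implies_behavior: bool = True

    def abbreviations(self) -> dict:
        return dict(self.abbreviation_map)

    def without_pattern(self, pattern: str) -> "PhenotypeLexicon":
        """Copy with every entry matching `pattern` removed (for audits)."""
        return replace(
            self,
            entries=tuple(e for e in self.entries if e.pattern != pattern),
        )


def load_default_lexicon() -> PhenotypeLexicon:
    """Load the bundled, editable complication terminology."""
    raw = json.loads(
        resources.files("cdpheno.assets").joinpath("lexicon.json").read_text("utf-8")
    )
    entries: List[LexiconEntry] = []
    for e in raw["string_entries"]:
        entries.append(
            LexiconEntry(
                pattern=e["pattern"],
                category=e["category"],
                route="string",
                implies_behavior=e.get("implies_behavior"),
            )
        )
    for c in raw["concepts"]:
        implies_syn = set(c.get("implies_behavior_synonyms", ()))
        for syn in c["synonyms"]:
            entries.append(
                LexiconEntry(
                    pattern=syn,
                    category=c["category"],
                    route="concept",
                    concept_id=c["concept_id"],
                    implies_behavior="B3" if syn in implies_syn else None,
                )
            )
    return PhenotypeLexicon(
        entries=tuple(entries),
        abbreviation_map=tuple(sorted(raw.get("abbreviations", {}).items())),
    )


# --------------------------------------------------------------------------
# Negation / context-exclusion configuration


@dataclass(frozen=True)
class NegationConfig:
    pre_triggers: Tuple[str, ...]
    post_triggers: Tuple[str, ...]
    scope_terminators: Tuple[str, ...]
    max_scope_tokens: int = 6

    def __post_init__(self):
        if not self.pre_triggers or not self.post_triggers:
            raise ValueError("trigger lists must be non-empty")
        if self.max_scope_tokens < 1:
            raise ValueError("max_scope_tokens must be >= 1")


def load_default_negation_config() -> NegationConfig:
    raw = json.loads(
        resources.files("cdpheno.assets").joinpath("negation.json").read_text("utf-8")
    )
    return NegationConfig(
        pre_triggers=tuple(raw["pre_triggers"]),
        post_triggers=tuple(raw["post_triggers"]),
        scope_terminators=tuple(raw["scope_terminators"]),
        max_scope_tokens=int(raw["max_scope_tokens"]),
    )


DEFAULT_NON_TARGET_CONTEXT_TERMS = frozenset(
    {
        "carotid",
        "aortic",
        "coronary",
        "spinal",
        "mitral",
        "tracheal",
        "urethral",
        "ureteral",
        "lacrimal",
        "nasolacrimal",
        "biliary",
    }
)


@dataclass(frozen=True)
class ContextExclusionConfig:
    non_target_context_terms: frozenset = DEFAULT_NON_TARGET_CONTEXT_TERMS
    window_tokens: int = 6

    def __post_init__(self):
        if self.window_tokens < 0:
            raise ValueError("window_tokens must be >= 0")


# --------------------------------------------------------------------------
# Stage 1: abbreviation expansion


@dataclass(frozen=True)
class AbbreviationExpansion:
    char_start: int
    char_end: int
    short_form: str
    expansion: str


def expand_abbreviations(
    sentence: Sentence, lexicon: PhenotypeLexicon
) -> List[AbbreviationExpansion]:
    """Annotate known short forms with their expansions; offsets preserved.

    Expansions are overlay annotations, never destructive edits, so every
    downstream span still indexes the original sentence text.  Matching is
    case-sensitive on the short form (clinical abbreviations are cased).
    """
    amap = lexicon.abbreviations()
    out = []
    for m in _TOKEN_RE.finditer(sentence.text):
        short = sentence.text[m.start() : m.end()]
        if short in amap:
            out.append(
                AbbreviationExpansion(m.start(), m.end(), short, amap[short])
            )
    return out


# --------------------------------------------------------------------------
# Stage 2: mention matching


def _find_token_subseq(
    tokens: Sequence[Tuple[str, int, int]], needle: Tuple[str, ...]
) -> List[Tuple[int, int]]:
    """Character spans of every occurrence of `needle` as consecutive tokens."""
    n = len(needle)
    spans = []
    for i in range(len(tokens) - n + 1):
        if all(tokens[i + j][0] == needle[j] for j in range(n)):
            spans.append((tokens[i][1], tokens[i + n - 1][2]))
    return spans


def match_mentions(
    sentence: Sentence, lexicon: PhenotypeLexicon
) -> List[PhenotypeMention]:
    """Dual-route mention matching over a sentence.

    Returns mentions with assertion unset.  String and concept routes are
    unioned; abbreviation expansions are searched too (a hit inside an
    expansion yields a mention over the short form's span).  Overlapping
    matches of the same category are merged to the widest span, preferring
    the string route on ties.
    """
    tokens = tokenize(sentence.text)
    expansions = expand_abbreviations(sentence, lexicon)

    raw: List[PhenotypeMention] = []
    for entry in lexicon.entries:
        needle = _term_tokens(entry.pattern)
        if not needle:
            continue
        for start, end in _find_token_subseq(tokens, needle):
            raw.append(
                PhenotypeMention(
                    note_id=sentence.note_id,
                    sentence_index=sentence.index,
                    char_start=start,
                    char_end=end,
                    matched_text=sentence.text[start:end],
                    category=entry.category,
                    match_route=entry.route,
                    implies_behavior=entry.implies_behavior,
                )
            )
        # same term inside an abbreviation expansion
        for exp in expansions:
            exp_tokens = _term_tokens(exp.expansion)
            n = len(needle)
            if any(
                exp_tokens[i : i + n] == needle
                for i in range(len(exp_tokens) - n + 1)
            ):
                raw.append(
                    PhenotypeMention(
                        note_id=sentence.note_id,
                        sentence_index=sentence.index,
                        char_start=exp.char_start,
                        char_end=exp.char_end,
                        matched_text=exp.short_form,
                        category=entry.category,
                        match_route=entry.route,
                        implies_behavior=entry.implies_behavior,
                    )
                )

    # merge overlapping same-category mentions to the widest span
    merged: List[PhenotypeMention] = []
    for category in ("B2", "B3", "perianal"):
        group = sorted(
            (m for m in raw if m.category == category),
            key=lambda m: (m.char_start, -(m.char_end - m.char_start)),
        )
        cluster: List[PhenotypeMention] = []
        for m in group:
            if cluster and m.char_start < max(c.char_end for c in cluster):
                cluster.append(m)
            else:
                if cluster:
                    merged.append(_merge_cluster(cluster, sentence))
                cluster = [m]
        if cluster:
            merged.append(_merge_cluster(cluster, sentence))
    merged.sort(key=lambda m: (m.char_start, m.category))
    return merged


def _merge_cluster(
    cluster: List[PhenotypeMention], sentence: Sentence
) -> PhenotypeMention:
    if len(cluster) == 1:
        return cluster[0]
    start = min(m.char_start for m in cluster)
    end = max(m.char_end for m in cluster)
    longest = max(
        cluster,
        key=lambda m: (m.char_end - m.char_start, m.match_route == "string"),
    )
    implies = next((m.implies_behavior for m in cluster if m.implies_behavior), None)
    return PhenotypeMention(
        note_id=cluster[0].note_id,
        sentence_index=cluster[0].sentence_index,
        char_start=start,
        char_end=end,
        matched_text=sentence.text[start:end],
        category=cluster[0].category,
        match_route=longest.match_route,
        implies_behavior=implies,
    )


# --------------------------------------------------------------------------
# Stage 3: assertion classification

#: signature any pluggable assertion classifier must satisfy
AssertionClassifier = Callable[[Sentence, PhenotypeMention, NegationConfig], str]


def _trigger_spans(
    tokens: Sequence[Tuple[str, int, int]], triggers: Sequence[str]
) -> List[Tuple[int, int, int, int]]:
    """(tok_start_idx, tok_end_idx, char_start, char_end) per trigger hit."""
    hits = []
    for trig in triggers:
        needle = _term_tokens(trig)
        n = len(needle)
        for i in range(len(tokens) - n + 1):
            if all(tokens[i + j][0] == needle[j] for j in range(n)):
                hits.append((i, i + n - 1, tokens[i][1], tokens[i + n - 1][2]))
    return hits


def classify_assertion(
    sentence: Sentence, mention: PhenotypeMention, config: NegationConfig
) -> str:
    """Rule-based NegEx-style assertion decision for one mention.

    A mention is negated iff a pre-trigger ends within ``max_scope_tokens``
    tokens before it (or a post-trigger starts within scope after it) with no
    scope terminator — a contrast conjunction or a ``;``/``:`` — in between.
    Anything else, including historical or resolved complications, is
    asserted: behavior is maximal over disease history.
    """
    tokens = tokenize(sentence.text)
    term_token_set = {_term_tokens(t) for t in config.scope_terminators}

    def idx_range(a: int, b: int) -> range:  # token indices strictly between
        return range(a, b)

    m_first = next(
        (i for i, (_, s, _e) in enumerate(tokens) if s >= mention.char_start), None
    )
    m_last = max(
        (i for i, (_, _s, e) in enumerate(tokens) if e <= mention.char_end),
        default=None,
    )
    if m_first is None or m_last is None or m_first > m_last:
        return "asserted"

    def blocked(lo_tok: int, hi_tok: int, lo_char: int, hi_char: int) -> bool:
        between = tokens[lo_tok:hi_tok]
        for n in range(1, 4):
            for i in range(len(between) - n + 1):
                if tuple(t for t, _, _ in between[i : i + n]) in term_token_set:
                    return True
        return bool(re.search(r"[;:]", sentence.text[lo_char:hi_char]))

    for i0, i1, c0, c1 in _trigger_spans(tokens, config.pre_triggers):
        if i1 < m_first and (m_first - i1 - 1) <= config.max_scope_tokens:
            if not blocked(i1 + 1, m_first, c1, mention.char_start):
                return "negated"
    for i0, i1, c0, c1 in _trigger_spans(tokens, config.post_triggers):
        if i0 > m_last and (i0 - m_last - 1) <= config.max_scope_tokens:
            if not blocked(m_last + 1, i0, mention.char_end, c0):
                return "negated"
    return "asserted"


# --------------------------------------------------------------------------
# Stage 4: anatomical-context exclusion


def apply_context_exclusion(
    sentence: Sentence,
    mention: PhenotypeMention,
    config: ContextExclusionConfig = ContextExclusionConfig(),
) -> bool:
    """True iff the mention sits in a non-intestinal anatomical context.

    Only B2/B3 mentions are subject to exclusion — perianal terms name their
    own location.  A mention is excluded when a non-target context term
    occurs within ``window_tokens`` tokens of the mention span.
    """
    if mention.category == "perianal":
        return False
    tokens = tokenize(sentence.text)
    terms = {t.lower() for t in config.non_target_context_terms}
    m_tok_idx = [
        i
        for i, (_, s, e) in enumerate(tokens)
        if s >= mention.char_start and e <= mention.char_end
    ]
    if not m_tok_idx:
        return False
    lo, hi = m_tok_idx[0], m_tok_idx[-1]
    for i, (tok, _, _) in enumerate(tokens):
        if tok in terms:
            dist = lo - i - 1 if i < lo else (i - hi - 1 if i > hi else 0)
            if dist <= config.window_tokens:
                return True
    return False


# --------------------------------------------------------------------------
# Composition


def analyze_sentence(
    sentence: Sentence,
    lexicon: PhenotypeLexicon,
    negation_config: NegationConfig,
    exclusion_config: ContextExclusionConfig = ContextExclusionConfig(),
    assertion_classifier: Optional[AssertionClassifier] = None,
) -> List[PhenotypeMention]:
    """Full mention pipeline; returns mentions with assertion and exclusion set."""
    classifier = assertion_classifier or classify_assertion
    out = []
    for m in match_mentions(sentence, lexicon):
        assertion = classifier(sentence, m, negation_config)
        excluded = apply_context_exclusion(sentence, m, exclusion_config)
        out.append(replace(m, assertion=assertion, excluded_by_context=excluded))
    return out


def classify_sentence(
    sentence: Sentence,
    lexicon: PhenotypeLexicon,
    negation_config: NegationConfig,
    exclusion_config: ContextExclusionConfig = ContextExclusionConfig(),
    assertion_classifier: Optional[AssertionClassifier] = None,
) -> SentenceLabel:
    """Derive the sentence's evidence label from asserted, in-context mentions."""
    mentions = analyze_sentence(
        sentence, lexicon, negation_config, exclusion_config, assertion_classifier
    )
    evidence = set()
    perianal = False
    for m in mentions:
        if m.assertion != "asserted" or m.excluded_by_context:
            continue
        if m.category in ("B2", "B3"):
            evidence.add(m.category)
        else:
            perianal = True
            if lexicon.perianal_implies_behavior and m.implies_behavior:
                evidence.add(m.implies_behavior)
    return SentenceLabel(
        note_id=sentence.note_id,
        sentence_index=sentence.index,
        behavior_evidence=frozenset(evidence),
        perianal=perianal,
    )
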