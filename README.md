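# cdpheno

Computable phenotyping of Crohn's disease (CD) from free-text clinical
notes. Chart review — reading a patient's record to assign Montreal
classification labels — does not scale; `cdpheno` automates it with a
transparent rule-based labeler, a pluggable LLM backend, and the evaluation
machinery to decide whether either can be trusted.

The package extracts, per sentence, per note and per patient:

- **Disease behavior** — Montreal B1 (non-stricturing, non-penetrating),
  B2 (stricturing: strictures, stenoses, luminal narrowing, obstruction),
  B3 (penetrating: fistulas, sinus tracts, abscesses, perforations),
  reported granularly and as the dichotomy **B2/B3 vs Not B2/B3**, with the
  most severe class winning under B1 < B2 < B3;
- **Perianal disease** — an independent yes/no modifier;
- **Age at diagnosis** — in years, from three surface forms (directly
  stated age; year of diagnosis; disease duration), resolved year-granular
  with an inherent ±1-year margin, with the earliest age selected across a
  patient's notes, and the Montreal age class (A1 ≤16, A2 17–40, A3 >40).

Two labelers share one contract: a rule pipeline (dual string+concept
terminology matching, NegEx-style negation with a pluggable assertion
classifier, anatomical-context exclusion) and an LLM adapter (few-shot
prompt, strict structured output, deterministic offline mock backend).
Their outputs can be fused with **AND** (agreement only, disagreements
queued for review) or **OR** (union of positives) policies, and compared
via per-class recall/precision/specificity/F1, Cohen's κ with Z-tests on κ
differences (Benjamini–Hochberg q-values), and Pearson correlation of
extracted vs gold ages.

Real clinical notes are protected health information, so the package ships
a seeded synthetic-corpus generator that emulates the statistical structure
of such a corpus — complication mentions in asserted, negated, confounded
(e.g. "carotid stenosis") and out-of-vocabulary forms, age statements in
the three surface forms at a 60:23:10 mix — with exact gold labels at all
three levels. See `docs/methods.md` for the full model description and
what synthetic results do and do not show.

## Worked example

```python
from cdpheno import (
    ClinicalNote, PreprocessConfig, classify_sentence, segment_sentences,
    load_default_lexicon, load_default_negation_config, aggregate_note,
)
import datetime

note = ClinicalNote(
    patient_id="p1", note_id="n1", note_datetime=datetime.date(2019, 5, 2),
    note_type="progress note",
    text=("Follow-up for Crohn's disease, diagnosed at age 24. "
          "MRI reveals a perianal fistula with seton in place. "
          "No stricture is seen."),
)
lexicon = load_default_lexicon()
negation = load_default_negation_config()
labels = [classify_sentence(s, lexicon, negation) for s in segment_sentences(note)]
for lab in labels:
    print(lab.sentence_index, sorted(lab.behavior_evidence), lab.perianal)
print(aggregate_note(labels, note).behavior)
```

prints

```
0 [] False
1 ['B3'] True
2 [] False
B3
```

Sentence 1 contributes penetrating (B3) evidence *and* the perianal flag (a
perianal fistula is both); the negated stricture in sentence 2 contributes
nothing; the note label is the most severe asserted class, B3. Running the
age extractor on sentence 0 yields a direct-age statement resolving to 24.0
years (Montreal A2).

The same flow runs end to end from the shell:

```sh
cdpheno run --seed 7 --out artifacts/
```

which generates a synthetic corpus, filters it, runs both labelers and both
ensembles, and writes label tables, a chart-review queue and evaluation
reports (`eval/metrics.csv`, `eval/age_metrics.csv`, `eval/agreement.csv`)
plus a checksummed run manifest; re-running with the same seed reproduces
every file byte-identically. Each stage is also available as its own
subcommand (`simulate`, `preprocess`, `phenotype-behavior`,
`phenotype-llm`, `extract-age`, `ensemble`, `evaluate`).

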