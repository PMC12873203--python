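# Methods

`cdpheno` implements computable phenotyping of Crohn's disease (CD) from
free-text clinical notes: assignment of Montreal behavior (B1
non-stricturing/non-penetrating, B2 stricturing, B3 penetrating, reported
both granularly and as the B2/B3 vs Not B2/B3 dichotomy), the perianal
disease modifier (yes/no), and the age at initial diagnosis in years. This
note documents the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Preprocessing

Notes pass three filters before extraction. (1) Empty notes and
administrative note types (telephone encounters, patient instructions, and
an extensible exclusion list) are dropped; (2) a note must contain at least
one disease-context term (case-insensitive regex over the whole note:
`crohn`, `\bibd\b`, `inflammatory bowel`, ...). Every dropped note is
logged with exactly one reason, so `|kept| + |dropped| = |input|` and the
filter is auditable and idempotent. (3) For age extraction only, a cheap
keyword prefilter (`diagnos`, `crohn…since`, `age at`, ...) gates the more
expensive pattern pass; it is recall-oriented by design and its recall is
1.0 on generated corpora by construction of the pattern list.

Sentence segmentation is a deterministic rule engine: breaks on `.!?` runs
followed by whitespace and on newlines, with a shipped no-break
abbreviation list (`Dr.`, `b.i.d.`, `vs.`, ...) and protection for
intra-token periods (`3.5 cm`). What is contractual is the output — 0-based
half-open character offsets, non-overlapping ordered sentences whose spans
jointly cover all non-whitespace text — not the engine; a different
splitter honoring the same contract can be substituted.

## Behavior extraction (rule-based)

Per sentence, four stages:

1. **Abbreviation expansion.** Known short forms (`RVF`, `ECF`, `SBO`, ...)
   are annotated with expansions as overlays; offsets always index the
   original text.
2. **Dual-route matching.** A surface-string route (explicit word patterns,
   token-boundary-respecting, case-insensitive) and a concept route (an
   editable terminology dictionary with per-concept synonym lists) are
   unioned. The bundled dictionary covers stricture/stenosis/
   narrowing/obstruction (B2), fistula/sinus tract/abscess/perforation/
   phlegmon (B3) and perianal fistula/abscess, anal fissure, seton,
   perianal disease (perianal). Overlapping same-category matches merge to
   the widest span. The dictionary is a self-contained reconstruction of
   the category semantics — deliberately editable plain JSON rather than a
   licensed vocabulary, so the matching contract is fully reproducible.
3. **Assertion.** A NegEx/ConText-style rule: a mention is negated iff a
   pre-trigger ("no", "denies", "no evidence of", ...) ends within
   `max_scope_tokens` (default 6) tokens before it, or a post-trigger
   ("was ruled out", ...) starts within scope after it, with no scope
   terminator ("but", "however", `;`, `:`) in between. Ties resolve in
   favor of assertion when no pre-trigger is in scope. Historical or
   resolved complications count as asserted: Montreal behavior is maximal
   over the disease history, so "history of fistula, resolved" is B3
   evidence. The classifier is pluggable — any callable with the signature
   `(sentence, mention, config) -> "asserted"|"negated"` (e.g. a
   statistical assertion model) can be injected everywhere the rule is
   used, with no other code change.
4. **Context exclusion.** B2/B3 mentions within `window_tokens` (default 6)
   of a non-intestinal anatomical term (`carotid`, `aortic`, `spinal`, ...)
   are discarded: "carotid stenosis" is not CD behavior. Perianal terms
   name their own location and are never excluded.

A perianal complication that is itself a penetrating lesion (perianal
fistula/abscess) also contributes B3 evidence; the two labels genuinely
co-occur and conflating or separating them is a modelling choice, so it is
exposed as a lexicon flag (`perianal_implies_behavior`, default on).

## Age at diagnosis

Three surface forms are extracted: a directly stated age ("diagnosed … at
age 25"), a diagnosis year ("Crohn's disease since 2005"), and a disease
duration ("18-month history of Crohn's"). Year and duration statements
resolve against a reference context: the note year (note-level) or
enrollment year (patient-level) together with the patient's age at that
reference and/or birth year. Resolution is year-granular — exact dates are
rarely written — so a ±1-year margin is inherent and every downstream
comparison uses it. Consequences of that choice: fractional ages from month
durations are kept unrounded (rounding would double-count the margin), and
vague decade statements ("in his 20s") are not extracted at all, since they
cannot be resolved to ±1 year. Implausible values (years outside
1900–note-year, ages outside 0–120) are discarded with a log entry rather
than raised. Within a note, multiple resolvable statements take the
minimum, flagged discordant when they span more than 1 year — the same
earliest-age rule used at patient level, applied one level down.

## Aggregation

Sentence → note: behavior is the most severe class among the asserted
evidence under B1 < B2 < B3, with B1 as the closed-world default;
perianal is "yes" iff any sentence asserts it; contributing sentence
indices are kept as provenance and the note timestamp is carried. Note →
patient: the same maximum over notes, the earliest age across note-level
results, and the Montreal age class (A1 ≤ 16, A2 17–40, A3 > 40, fractional
ages floored so 16.5 stays A1). An optional cutoff date (typically study
enrollment) restricts which notes count; the default is no cutoff, and both
modes are supported because automated labels and chart review may legitimately
be computed over different time windows. Both roll-ups are
permutation-invariant, idempotent, and monotone: adding a note can only
raise severity or lower the diagnosis age.

## LLM adapter

The note-level LLM labeler is specified as a backend contract: a prompt
built deterministically from condensed annotation guidelines, exactly three
worked examples (order fixed by seed, not by caller order), the target
note, and a strict output-format instruction; the response is a flat
payload (`behavior`, `perianal`, optional consistent `behavior_binary`)
that maps 1:1 onto a note label. Invalid payloads raise typed errors
(missing field / unknown field / bad enum / malformed) — never a silent
default. Temperature is 0 in the shipped config. Only a deterministic mock
backend ships enabled: a keyword heuristic over the target-note section
reusing the bundled lexicon and negation triggers but — deliberately —
no context exclusion, so the mock and the rules disagree on confounder
sentences and the ensemble and agreement machinery is exercised on real
disagreements. The mock is a test double and makes no claim about any real
model's behavior. A live adapter can be registered behind the same
interface; clinical text sent to a remote API leaves the local system,
which is why the live path is opt-in and isolated.

## Ensembles and review prioritization

AND keeps a label only where both labelers agree on the dichotomy and the
perianal flag; discordant instances are retained with an explicit flag
(excluded from AND metrics but never dropped, so AND coverage is computable
from the artifact's own outputs). OR takes the union of positives. On any
corpus, AND-positives ⊆ rules-positives ∩ LLM-positives and OR recall
dominates both components; both laws are property-tested. The review queue
ranks discordant patients first, then concordant positives by descending
complication-positive note count, then concordant negatives, ties broken by
patient id. Counts order patients *within* strata only — they are never a
classifier, because patients with known complications can have zero
positive notes.

## Evaluation

Per-class one-vs-rest confusion counting (classes: B2/B3, Not B2/B3,
perianal-yes, perianal-no) with recall, precision, specificity and F1;
instances missing from a labeler's output count as FN when gold-positive,
TN otherwise. Zero denominators yield "undefined", never 0. Age evaluation
uses asymmetric definitions: prediction within ±1 year of gold → TP; both
absent → TN; a wrong value, or a value where gold has none → FP; no
prediction where gold has a value ("overlooked") → FN. A wrong value is an
FP only — recall is therefore insensitive to wrong values, which is
deliberate and matters when reading high recall figures.

Agreement is Cohen's κ = (pₒ−pₑ)/(1−pₑ) with the large-sample standard
error √(pₒ(1−pₒ)/(n(1−pₑ)²)); κ is undefined (not 1, not 0) when both
raters are constant and equal. Which variance estimator to use is an open
choice; this one is documented here and isolated in one function so it can
be swapped. Kappa differences are compared with z = (κ₁−κ₂)/√(SE₁²+SE₂²),
two-sided normal p, and Benjamini–Hochberg q-values across all requested
comparisons (the BH step is the identity for a single comparison). Age
correlation is the Pearson coefficient over complete pairs (≥3 required;
zero variance → undefined).

All metric operations are verified against independent brute-force
implementations (dict counting, literal formulas) on hundreds of seeded
random corpora.

## Synthetic corpus generator

The generator defines the study conditions for all end-to-end tests, since
real clinical notes cannot ship. Defaults: 100 patients, 8–12 notes each,
patient-level prevalences B2 0.30 / B3 0.20 / perianal 0.15 (plausible for
a tertiary-center CD cohort), mention probability 0.35 per note and
complication, 10% of rendered mentions negated, 5% of notes carrying a
non-intestinal confounder, 5% administrative and 3% context-free notes, and
an age-statement mix of 60% diagnosis year : 23% direct age : 10% duration
(remainder none). Note dates fall in a configurable window around
enrollment (default the 4 years before), so cutoff logic is exercisable.
Templates are tiered — unambiguous / negated / confounder / out-of-lexicon
— so tests can assert perfect recovery on tier 1 and measured degradation
when the out-of-lexicon rate is raised. Gold labels are exact by
construction and recorded at all three levels; they reflect what the
rendered text asserts, not the latent flags, because a patient whose notes
never mention a complication is indistinguishable from a negative patient
by any reader of those notes. The latent truth (birth year, diagnosis age
and year, complication flags) is stored in the manifest, and the rendered
age statements are mutually consistent with it in all three surface forms.

What the generator does **not** emulate: real clinical language variety,
section structure, templated auto-text, misspellings, copy-forward
duplication, or genuinely ambiguous phenotype descriptions (inflammatory
vs fibrotic stenosis, inactive complications). Perfect scores on tier-1
corpora therefore demonstrate the internal consistency of the pipeline —
extraction inverts generation exactly — not expected performance on real
notes.

## Problem sizes and numerics

Default test and demonstration corpora use 100 patients (~1000 notes), a
size at which binomial/multinomial checks on generator statistics have
usable power while the full suite stays fast; the metric-oracle sweep uses
200 random corpora of 50–500 instances, and the κ-calibration check uses
50 replicates of n=10⁴ independent labelings (mean κ within 3·SE/√50 of
0). All randomness flows from explicit integer seeds; same seed ⇒
byte-identical corpora and pipeline artifacts (checksummed in the run
manifest). Floating-point comparisons against the brute-force oracles use
1e-12; integer counts must match exactly.

## Known limitations

- The terminology dictionary is intentionally small; real deployments
  would extend it (it is plain JSON) or link to a licensed vocabulary.
- Negation handling is trigger/scope based; complex syntactic negation
  ("cannot exclude a fistula") is out of reach of the rule and is exactly
  the kind of case a plugged statistical assertion classifier should fix.
- Disease location (Montreal L1–L4) is not extracted.
- Phenotype *timing* is not modelled: aggregation yields the maximal
  behavior over the available history, not when transitions occurred.
- Patient-level results can overestimate complications when aggregating
  long histories without a cutoff; pass the enrollment date as cutoff when
  comparing against enrollment-time chart review.
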