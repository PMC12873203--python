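"""End-to-end pipeline: simulate → preprocess → label (rules + LLM backend)
→ extract age → aggregate → ensemble/prioritize → evaluate.

Stages communicate only via files with documented schemas, so any stage can
be re-run or swapped in isolation; :func:`run_pipeline` wires them in order
and writes a manifest with the seed, configs and a checksum per artifact.
With the mock backend the whole run is deterministic: same seed → byte
identical artifact directory.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from . import __version__
from .age_rules import AgePatternSet, extract_age_evidence, resolve_note_age
from .aggregate import aggregate_note, aggregate_patient
from .behavior_rules import (
    ContextExclusionConfig,
    classify_sentence,
    load_default_lexicon,
    load_default_negation_config,
)
from .data_model import (
    AgeResult,
    BINARY_NEGATIVE,
    BINARY_POSITIVE,
    ClinicalNote,
    Demographics,
    NoteLabel,
    PatientLabel,
    ReferenceContext,
    SentenceLabel,
    write_labels,
    write_notes,
)
from .ensemble import EnsembleLabel, combine_corpus, prioritize_for_review
from .evaluate import (
    age_confusion,
    class_metrics,
    cohens_kappa,
    compare_kappas,
    confusion_counts,
    pearson_correlation,
)
from .llm_adapter import DEFAULT_EXAMPLES, LLMConfig, label_notes
from .preprocess import (
    PreprocessConfig,
    filter_notes,
    prefilter_age_notes,
    segment_sentences,
)
from .synthgen import Corpus, GeneratorConfig, generate_corpus

logger = logging.getLogger(__name__)

BEHAVIOR_EVAL_CLASSES = (BINARY_POSITIVE, BINARY_NEGATIVE, "perianal-yes", "perianal-no")


# --------------------------------------------------------------------------
# Stage helpers (also the library surface the CLI subcommands call)


def label_corpus_rules(
    notes: Sequence[ClinicalNote],
    assertion_classifier=None,
) -> Tuple[List[SentenceLabel], List[NoteLabel]]:
    """Sentence-level rule labeling plus the note-level roll-up."""
    lexicon = load_default_lexicon()
    negation = load_default_negation_config()
    exclusion = ContextExclusionConfig()
    sentence_labels: List[SentenceLabel] = []
    note_labels: List[NoteLabel] = []
    for note in notes:
        labels = [
            classify_sentence(
                s, lexicon, negation, exclusion, assertion_classifier
            )
            for s in segment_sentences(note)
        ]
        sentence_labels.extend(labels)
        note_labels.append(aggregate_note(labels, note, source="rules"))
    return sentence_labels, note_labels


def extract_corpus_ages(
    notes: Sequence[ClinicalNote],
    demographics: Dict[str, Demographics],
    config: PreprocessConfig = PreprocessConfig(),
    patterns: AgePatternSet = AgePatternSet(),
) -> Dict[str, AgeResult]:
    """Note-level age extraction over the age-prefiltered corpus."""
    results: Dict[str, AgeResult] = {}
    for note in prefilter_age_notes(notes, config):
        demo = demographics.get(note.patient_id)
        birth = demo.birth_year if demo else None
        context = ReferenceContext(
            reference_year=note.note_year,
            age_at_reference=(
                None if birth is None else float(note.note_year - birth)
            ),
            birth_year=birth,
        )
        evidences = []
        for sentence in segment_sentences(note, config.abbreviations):
            evidences.extend(
                extract_age_evidence(sentence, patterns, note_year=note.note_year)
            )
        result = resolve_note_age(evidences, context)
        if result is not None:
            results[note.note_id] = result
    return results


def aggregate_patients(
    note_labels: Sequence[NoteLabel],
    note_ages: Dict[str, AgeResult],
    cutoff_dates: Optional[Dict[str, object]] = None,
    source: str = "rules",
) -> List[PatientLabel]:
    by_patient: Dict[str, List[NoteLabel]] = {}
    for nl in note_labels:
        by_patient.setdefault(nl.patient_id, []).append(nl)
    note_dates = {nl.note_id: nl.note_datetime for nl in note_labels}
    out = []
    for pid in sorted(by_patient):
        notes = by_patient[pid]
        ids = {n.note_id for n in notes}
        ages = [note_ages[i] for i in sorted(ids) if i in note_ages]
        out.append(
            aggregate_patient(
                notes,
                ages,
                cutoff_date=(cutoff_dates or {}).get(pid),
                age_result_dates=note_dates,
                source=source,
            )
        )
    return out


# --------------------------------------------------------------------------
# Evaluation tables


def _behavior_value(label, cls: str) -> str:
    if cls in (BINARY_POSITIVE, BINARY_NEGATIVE):
        return label.behavior_binary
    return "perianal-yes" if label.perianal else "perianal-no"


def behavior_metric_rows(
    pred_labels: Sequence, gold_labels: Sequence, model: str, level: str
) -> List[dict]:
    """Per-class one-vs-rest metric rows for one model at one level."""
    key = (
        (lambda l: l.note_id) if level == "note" else (lambda l: l.patient_id)
    )
    rows = []
    for cls in BEHAVIOR_EVAL_CLASSES:
        pred = [(key(l), _behavior_value(l, cls)) for l in pred_labels]
        gold = [(key(l), _behavior_value(l, cls)) for l in gold_labels]
        counts = confusion_counts(pred, gold, cls)
        m = class_metrics(counts)
        rows.append(
            {
                "level": level,
                "task": "behavior",
                "model": model,
                "class": cls,
                "tp": counts.tp,
                "fp": counts.fp,
                "fn": counts.fn,
                "tn": counts.tn,
                "recall": m.recall,
                "precision": m.precision,
                "specificity": m.specificity,
                "f1": m.f1,
            }
        )
    return rows


def age_metric_rows(
    pred_ages: Dict[str, Optional[float]],
    gold_ages: Dict[str, Optional[float]],
    model: str,
    level: str,
) -> List[dict]:
    counts = age_confusion(pred_ages, gold_ages)
    m = class_metrics(counts)
    try:
        corr = pearson_correlation(pred_ages, gold_ages)
        r, n_pairs = corr.r, corr.n
    except ValueError:
        r, n_pairs = None, 0
    return [
        {
            "level": level,
            "task": "age_at_diagnosis",
            "model": model,
            "class": "age",
            "tp": counts.tp,
            "fp": counts.fp,
            "fn": counts.fn,
            "tn": counts.tn,
            "recall": m.recall,
            "precision": m.precision,
            "specificity": m.specificity,
            "f1": m.f1,
            "pearson_r": r,
            "n_pairs": n_pairs,
        }
    ]


def agreement_rows(
    labelings: Dict[str, Sequence[str]], compare: Sequence[Tuple[str, str]]
) -> List[dict]:
    """Cohen's kappa per labeler pair plus Z-tests on requested differences.

    `labelings` maps a labeler name to its label sequence (all aligned);
    kappa is computed for every unordered pair, and `compare` names pairs of
    *kappa results* to difference-test (e.g. rules-vs-gold against
    llm-vs-gold), BH-adjusted across all requested comparisons.
    """
    names = sorted(labelings)
    pair_names = [
        f"{a}|{b}" for i, a in enumerate(names) for b in names[i + 1 :]
    ]
    results = {}
    for pair in pair_names:
        a, b = pair.split("|")
        results[pair] = cohens_kappa(labelings[a], labelings[b])
    rows = [
        {
            "pair": pair,
            "kappa": res.kappa,
            "p_observed": res.p_observed,
            "p_expected": res.p_expected,
            "se": res.se,
            "n": res.n,
            "z": None,
            "p": None,
            "q": None,
        }
        for pair, res in results.items()
    ]
    ordered = list(results)
    idx_pairs = []
    for a, b in compare:
        if (
            a in results
            and b in results
            and results[a].kappa is not None
            and results[b].kappa is not None
        ):
            idx_pairs.append((ordered.index(a), ordered.index(b)))
    if idx_pairs:
        compared = compare_kappas([results[k] for k in ordered], idx_pairs)
        for (i, j), res in zip(idx_pairs, compared):
            rows.append(
                {
                    "pair": f"diff[{ordered[i]} - {ordered[j]}]",
                    "kappa": None,
                    "p_observed": None,
                    "p_expected": None,
                    "se": None,
                    "n": None,
                    "z": res.z,
                    "p": res.p,
                    "q": res.q,
                }
            )
    return rows


# --------------------------------------------------------------------------
# File helpers


def _write_rows(rows: List[dict], path: Path) -> None:
    if not rows:
        path.write_text("", encoding="utf-8")
        return
    cols = list(rows[0].keys())
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(cols)
        for row in rows:
            writer.writerow(
                ["" if row.get(c) is None else row.get(c) for c in cols]
            )


def _write_ensemble(labels: Sequence[EnsembleLabel], path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            ["id", "behavior", "behavior_binary", "perianal", "source", "discordant"]
        )
        for e in labels:
            lab = e.label
            lab_id = lab.note_id if isinstance(lab, NoteLabel) else lab.patient_id
            writer.writerow(
                [
                    lab_id,
                    lab.behavior,
                    lab.behavior_binary,
                    "yes" if lab.perianal else "no",
                    lab.source,
                    "yes" if e.discordant else "no",
                ]
            )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# --------------------------------------------------------------------------
# The end-to-end run


def run_pipeline(
    out_dir: Path,
    seed: int = 0,
    generator_config: Optional[GeneratorConfig] = None,
    preprocess_config: Optional[PreprocessConfig] = None,
    backend_id: str = "mock",
) -> Path:
    """Execute every stage on a freshly generated corpus; return `out_dir`.

    Artifacts land in subdirectories corpus/, preprocess/, labels/,
    ensemble/ and eval/, plus a run manifest with per-file checksums.
    A stage failure propagates with partial outputs retained on disk.
    """
    out_dir = Path(out_dir)
    gen_config = generator_config or GeneratorConfig(seed=seed)
    pp_config = preprocess_config or PreprocessConfig()
    for sub in ("corpus", "preprocess", "labels", "ensemble", "eval"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)

    # 1. simulate
    corpus = generate_corpus(gen_config, out_dir / "corpus")
    demographics = {d.patient_id: d for d in corpus.demographics}

    # 2. preprocess
    kept, drops = filter_notes(corpus.notes, pp_config)
    write_notes(kept, out_dir / "preprocess" / "kept.jsonl")
    _write_rows(
        [{"note_id": d.note_id, "reason": d.reason} for d in drops],
        out_dir / "preprocess" / "droplog.csv",
    )

    # 3. rule-based behavior labeling
    sent_rules, note_rules = label_corpus_rules(kept)
    write_labels(sent_rules, out_dir / "labels" / "sentence_rules.csv", "sentence")
    write_labels(note_rules, out_dir / "labels" / "note_rules.csv", "note")

    # 4. age extraction (rule-based)
    note_ages = extract_corpus_ages(kept, demographics, pp_config)
    _write_rows(
        [
            {
                "note_id": nid,
                "age_at_diagnosis": res.age_at_diagnosis,
                "discordant": "yes" if res.discordant else "no",
            }
            for nid, res in sorted(note_ages.items())
        ],
        out_dir / "labels" / "ages_note.csv",
    )

    # 5. patient aggregation (rules)
    patient_rules = aggregate_patients(note_rules, note_ages, source="rules")
    write_labels(patient_rules, out_dir / "labels" / "patient_rules.csv", "patient")

    # 6. LLM-backend labeling + aggregation
    llm_config = LLMConfig(backend_id=backend_id, seed=seed)
    note_llm = label_notes(kept, DEFAULT_EXAMPLES, config=llm_config)
    write_labels(note_llm, out_dir / "labels" / "note_llm.csv", "note")
    patient_llm = aggregate_patients(note_llm, {}, source="llm")
    # patient labels keep source=llm
    patient_llm = [dataclasses.replace(p, source="llm") for p in patient_llm]
    write_labels(patient_llm, out_dir / "labels" / "patient_llm.csv", "patient")

    # 7. ensembles + review queue
    ens_and_note = combine_corpus(note_rules, note_llm, "and")
    ens_or_note = combine_corpus(note_rules, note_llm, "or")
    ens_and_patient = combine_corpus(patient_rules, patient_llm, "and")
    ens_or_patient = combine_corpus(patient_rules, patient_llm, "or")
    _write_ensemble(ens_and_note, out_dir / "ensemble" / "and_note.csv")
    _write_ensemble(ens_or_note, out_dir / "ensemble" / "or_note.csv")
    _write_ensemble(ens_and_patient, out_dir / "ensemble" / "and_patient.csv")
    _write_ensemble(ens_or_patient, out_dir / "ensemble" / "or_patient.csv")
    queue = prioritize_for_review(patient_rules, patient_llm, note_rules, note_llm)
    queue.to_csv(out_dir / "ensemble" / "review_queue.csv", index=False)

    # 8. evaluation
    rows: List[dict] = []
    gold_note = corpus.gold_note
    gold_patient = corpus.gold_patient
    rows += behavior_metric_rows(note_rules, gold_note, "rules", "note")
    rows += behavior_metric_rows(note_llm, gold_note, "llm", "note")
    rows += behavior_metric_rows(
        [e.label for e in ens_and_note if not e.discordant],
        gold_note, "ensemble_and", "note",
    )
    rows += behavior_metric_rows(
        [e.label for e in ens_or_note], gold_note, "ensemble_or", "note"
    )
    rows += behavior_metric_rows(patient_rules, gold_patient, "rules", "patient")
    rows += behavior_metric_rows(patient_llm, gold_patient, "llm", "patient")
    rows += behavior_metric_rows(
        [e.label for e in ens_and_patient if not e.discordant],
        gold_patient, "ensemble_and", "patient",
    )
    rows += behavior_metric_rows(
        [e.label for e in ens_or_patient], gold_patient, "ensemble_or", "patient"
    )
    _write_rows(rows, out_dir / "eval" / "metrics.csv")

    pred_note_ages = {
        n.note_id: (
            note_ages[n.note_id].age_at_diagnosis if n.note_id in note_ages else None
        )
        for n in corpus.notes
    }
    age_rows = age_metric_rows(
        pred_note_ages, corpus.gold_note_ages, "rules", "note"
    )
    pred_patient_ages = {p.patient_id: p.age_at_diagnosis for p in patient_rules}
    gold_patient_ages = {p.patient_id: p.age_at_diagnosis for p in gold_patient}
    for pid in gold_patient_ages:
        pred_patient_ages.setdefault(pid, None)
    age_rows += age_metric_rows(
        pred_patient_ages, gold_patient_ages, "rules", "patient"
    )
    _write_rows(age_rows, out_dir / "eval" / "age_metrics.csv")

    kept_ids = [n.note_id for n in kept]
    gold_by_id = {g.note_id: g for g in gold_note}
    rules_by_id = {l.note_id: l for l in note_rules}
    llm_by_id = {l.note_id: l for l in note_llm}
    labelings = {
        "gold": [gold_by_id[i].behavior_binary for i in kept_ids],
        "rules": [rules_by_id[i].behavior_binary for i in kept_ids],
        "llm": [llm_by_id[i].behavior_binary for i in kept_ids],
    }
    agr = agreement_rows(
        labelings, compare=[("gold|rules", "gold|llm"), ("gold|rules", "llm|rules")]
    )
    _write_rows(agr, out_dir / "eval" / "agreement.csv")

    # 9. manifest (written last; sorted keys → byte-stable)
    files = sorted(
        p.relative_to(out_dir).as_posix()
        for p in out_dir.rglob("*")
        if p.is_file() and p.name != "run_manifest.json"
    )
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "backend_id": backend_id,
        "generator_config": dataclasses.asdict(gen_config),
        "checksums": {f: _sha256(out_dir / f) for f in files},
    }
    with open(out_dir / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out_dir
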