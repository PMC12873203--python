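"""AND/OR combination of the two labelers and chart-review prioritization.

Two fusion policies over the rule-based and LLM labels for the same
instance:

* AND — keep the label only where the two labelers agree on both the
  complication dichotomy (B2/B3 vs Not B2/B3) and the perianal modifier;
  disagreements are flagged discordant, excluded from AND metrics, and
  queued first for manual review.
* OR  — a complication counts if either labeler flags it (union of
  positives); maximal recall at the cost of precision.

Discordant AND instances are retained in the output with an explicit flag —
never silently dropped — so the AND coverage (the agreement fraction) is
always computable from the artifact's own files.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Union

import pandas as pd

from .data_model import (
    BINARY_POSITIVE,
    BEHAVIOR_SEVERITY,
    NoteLabel,
    PatientLabel,
)

Label = Union[NoteLabel, PatientLabel]


@dataclass(frozen=True)
class EnsembleLabel:
    """A fused label plus the discordance flag (AND policy only)."""

    label: Label
    discordant: bool = False


def _check_pair(a: Label, b: Label) -> str:
    if type(a) is not type(b):
        raise ValueError("cannot combine labels of different levels")
    id_a = a.note_id if isinstance(a, NoteLabel) else a.patient_id
    id_b = b.note_id if isinstance(b, NoteLabel) else b.patient_id
    if id_a != id_b:
        raise ValueError(f"id mismatch: {id_a!r} vs {id_b!r}")
    return id_a


def _more_severe(a: Label, b: Label) -> str:
    return max(a.behavior, b.behavior, key=lambda x: BEHAVIOR_SEVERITY[x])


def combine_and(label_rules: Label, label_llm: Label) -> EnsembleLabel:
    """Agreement-only fusion; disagreement → discordant flag."""
    _check_pair(label_rules, label_llm)
    agree = (
        label_rules.behavior_binary == label_llm.behavior_binary
        and label_rules.perianal == label_llm.perianal
    )
    # within an agreeing B2/B3 dichotomy the granular class may differ;
    # severity order resolves it
    behavior = (
        _more_severe(label_rules, label_llm) if agree else label_rules.behavior
    )
    fused = replace(label_rules, behavior=behavior, source="ensemble_and")
    if isinstance(fused, NoteLabel):
        fused = replace(fused, evidence=())
    return EnsembleLabel(label=fused, discordant=not agree)


def combine_or(label_rules: Label, label_llm: Label) -> Label:
    """Union-of-positives fusion: complication if either labeler says so."""
    _check_pair(label_rules, label_llm)
    fused = replace(
        label_rules,
        behavior=_more_severe(label_rules, label_llm),
        perianal=bool(label_rules.perianal or label_llm.perianal),
        source="ensemble_or",
    )
    if isinstance(fused, NoteLabel):
        fused = replace(fused, evidence=())
    return fused


def combine_corpus(
    labels_rules: Sequence[Label], labels_llm: Sequence[Label], mode: str
) -> List[EnsembleLabel]:
    """Pairwise combination over two aligned label sets (matched by id)."""
    if mode not in ("and", "or"):
        raise ValueError("mode must be 'and' or 'or'")
    key = lambda l: l.note_id if isinstance(l, NoteLabel) else l.patient_id
    by_id = {key(l): l for l in labels_llm}
    missing = [key(l) for l in labels_rules if key(l) not in by_id]
    if missing:
        raise ValueError(f"llm labels missing for ids: {missing[:5]}")
    out = []
    for lr in labels_rules:
        ll = by_id[key(lr)]
        if mode == "and":
            out.append(combine_and(lr, ll))
        else:
            out.append(EnsembleLabel(label=combine_or(lr, ll), discordant=False))
    return out


def prioritize_for_review(
    patient_rules: Sequence[PatientLabel],
    patient_llm: Sequence[PatientLabel],
    note_rules: Sequence[NoteLabel],
    note_llm: Sequence[NoteLabel],
) -> pd.DataFrame:
    """Rank patients for manual chart review.

    Discordant patients (the two labelers disagree on dichotomy or perianal)
    come first, then concordant complication-positive patients by descending
    complication-positive note count, then concordant negatives; ties break
    by patient_id.  Counts order patients within strata only — they are
    never used as a classifier, since patients with known complications can
    have zero positive notes.
    """
    llm_by_id = {p.patient_id: p for p in patient_llm}

    def pos_counts(notes: Sequence[NoteLabel]) -> dict:
        counts: dict = {}
        for n in notes:
            pos = n.behavior_binary == BINARY_POSITIVE or n.perianal
            counts[n.patient_id] = counts.get(n.patient_id, 0) + int(pos)
        return counts

    counts_rules = pos_counts(note_rules)
    counts_llm = pos_counts(note_llm)

    rows = []
    for pr in patient_rules:
        pl = llm_by_id.get(pr.patient_id)
        if pl is None:
            raise ValueError(f"no llm patient label for {pr.patient_id!r}")
        concordant = (
            pr.behavior_binary == pl.behavior_binary and pr.perianal == pl.perianal
        )
        positive = pr.behavior_binary == BINARY_POSITIVE or bool(pr.perianal)
        n_pos = counts_rules.get(pr.patient_id, 0) + counts_llm.get(pr.patient_id, 0)
        if not concordant:
            stratum = 0  # review first
        elif positive:
            stratum = 1
        else:
            stratum = 2
        rows.append(
            {
                "patient_id": pr.patient_id,
                "agreement": "concordant" if concordant else "discordant",
                "positive_notes_rules": counts_rules.get(pr.patient_id, 0),
                "positive_notes_llm": counts_llm.get(pr.patient_id, 0),
                "stratum": stratum,
                "_sort_count": n_pos,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=[
                "rank", "patient_id", "agreement",
                "positive_notes_rules", "positive_notes_llm",
            ]
        )
    df = df.sort_values(
        ["stratum", "_sort_count", "patient_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df.insert(0, "rank", range(1, len(df) + 1))
    return df.drop(columns=["stratum", "_sort_count"])
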