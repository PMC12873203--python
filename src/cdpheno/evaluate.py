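"""Evaluation protocol: per-class confusion metrics, age-specific
TP/FP/FN/TN rules, Cohen's kappa with a large-sample SE, kappa-difference
Z-tests with Benjamini–Hochberg q-values, and Pearson correlation of
extracted vs gold ages.

Degenerate denominators yield ``None`` ("undefined"), never a silent 0 —
small synthetic sets hit these cases constantly and coercing them to zero
would quietly distort averages.

Age evaluation follows asymmetric definitions: a prediction within ±1 year
of gold is a TP; a wrong value (or a value where gold has none) is a FP; an
*overlooked* gold value — no prediction at all — is a FN.  A wrong value is
therefore a FP only, which makes recall insensitive to wrong values; this
is deliberate and documented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ClassMetrics:
    recall: Optional[float]
    precision: Optional[float]
    specificity: Optional[float]
    f1: Optional[float]


@dataclass(frozen=True)
class AgreementResult:
    kappa: Optional[float]
    p_observed: float
    p_expected: float
    se: Optional[float]
    n: int
    z: Optional[float] = None
    p: Optional[float] = None
    q: Optional[float] = None


@dataclass(frozen=True)
class CorrelationResult:
    r: Optional[float]
    n: int


# --------------------------------------------------------------------------
# Confusion counting


def _check_unique(pairs: Sequence[Tuple[str, object]], name: str) -> Dict[str, object]:
    out: Dict[str, object] = {}
    for key, value in pairs:
        if key in out:
            raise ValueError(f"duplicate id in {name}: {key!r}")
        out[key] = value
    return out


def confusion_counts(
    pred: Sequence[Tuple[str, str]],
    gold: Sequence[Tuple[str, str]],
    positive_class: str,
) -> ConfusionCounts:
    """One-vs-rest confusion counts over (id, class) pairs.

    The gold set defines the evaluable instances.  An instance missing from
    the predictions counts as FN when gold is positive, else TN (a labeler
    that never saw the note cannot have flagged it).
    """
    pred_map = _check_unique(pred, "pred")
    gold_map = _check_unique(gold, "gold")
    tp = fp = fn = tn = 0
    for key, gold_value in gold_map.items():
        gold_pos = gold_value == positive_class
        if key not in pred_map:
            if gold_pos:
                fn += 1
            else:
                tn += 1
            continue
        pred_pos = pred_map[key] == positive_class
        if pred_pos and gold_pos:
            tp += 1
        elif pred_pos:
            fp += 1
        elif gold_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def class_metrics(counts: ConfusionCounts) -> ClassMetrics:
    """Recall, precision, specificity, F1; zero denominators → None."""

    def ratio(num: int, den: int) -> Optional[float]:
        return None if den == 0 else num / den

    recall = ratio(counts.tp, counts.tp + counts.fn)
    precision = ratio(counts.tp, counts.tp + counts.fp)
    specificity = ratio(counts.tn, counts.tn + counts.fp)
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return ClassMetrics(
        recall=recall, precision=precision, specificity=specificity, f1=f1
    )


def age_confusion(
    pred_ages: Mapping[str, Optional[float]],
    gold_ages: Mapping[str, Optional[float]],
    tolerance: float = 1.0,
) -> ConfusionCounts:
    """Confusion counts for nullable age values under a ±tolerance match.

    both present & |Δ| ≤ tol → TP;   both absent → TN;
    pred present & (gold absent or |Δ| > tol) → FP;
    pred absent & gold present → FN.
    """
    tp = fp = fn = tn = 0
    for key, gold_value in gold_ages.items():
        pred_value = pred_ages.get(key)
        if pred_value is None and gold_value is None:
            tn += 1
        elif pred_value is None:
            fn += 1
        elif gold_value is None or abs(pred_value - gold_value) > tolerance:
            fp += 1
        else:
            tp += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


# --------------------------------------------------------------------------
# Agreement


def cohens_kappa(
    labels_a: Sequence[object],
    labels_b: Sequence[object],
    categories: Optional[Sequence[object]] = None,
) -> AgreementResult:
    """Cohen's kappa between two complete labelings of the same instances.

    κ = (pₒ − pₑ) / (1 − pₑ) with pₑ from the product of marginals.  The
    standard error is the large-sample formula
    SE = sqrt(pₒ(1 − pₒ) / (n (1 − pₑ)²)), adequate for the Z-tests on
    kappa differences; pass the result through :func:`compare_kappas` to
    fill z/p/q.  When both raters are constant and equal (pₑ = 1) kappa is
    undefined and reported as None.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"labelings differ in length: {len(labels_a)} vs {len(labels_b)}"
        )
    n = len(labels_a)
    if n == 0:
        raise ValueError("empty labelings")
    cats = list(categories) if categories is not None else sorted(
        set(labels_a) | set(labels_b), key=repr
    )
    index = {c: i for i, c in enumerate(cats)}
    unknown = (set(labels_a) | set(labels_b)) - set(index)
    if unknown:
        raise ValueError(f"labels outside the category set: {sorted(map(repr, unknown))}")
    table = np.zeros((len(cats), len(cats)))
    for a, b in zip(labels_a, labels_b):
        table[index[a], index[b]] += 1
    table /= n
    p_o = float(np.trace(table))
    p_e = float(table.sum(axis=1) @ table.sum(axis=0))
    if math.isclose(p_e, 1.0):
        return AgreementResult(
            kappa=None, p_observed=p_o, p_expected=p_e, se=None, n=n
        )
    kappa = (p_o - p_e) / (1 - p_e)
    se = math.sqrt(p_o * (1 - p_o) / (n * (1 - p_e) ** 2))
    return AgreementResult(kappa=kappa, p_observed=p_o, p_expected=p_e, se=se, n=n)


def compare_kappas(
    results: Sequence[AgreementResult], pairs: Sequence[Tuple[int, int]]
) -> List[AgreementResult]:
    """Z-tests on kappa differences with BH-adjusted q-values.

    For each requested (i, j) pair, z = (κᵢ − κⱼ) / sqrt(SEᵢ² + SEⱼ²) with a
    two-sided normal p; q-values are Benjamini–Hochberg across all pairs.
    Returns one result per pair, carrying the first member's kappa and the
    filled z/p/q.  Kappas are assumed to come from independent samples.
    """
    if not pairs:
        return []
    zs, ps = [], []
    for i, j in pairs:
        a, b = results[i], results[j]
        if a.kappa is None or b.kappa is None:
            raise ValueError("cannot compare an undefined kappa")
        var = (a.se or 0.0) ** 2 + (b.se or 0.0) ** 2
        if var == 0:
            raise ValueError("both standard errors are zero")
        z = (a.kappa - b.kappa) / math.sqrt(var)
        zs.append(z)
        ps.append(2 * stats.norm.sf(abs(z)))
    qs = multipletests(ps, method="fdr_bh")[1]
    out = []
    for (i, j), z, p, q in zip(pairs, zs, ps, qs):
        out.append(replace(results[i], z=z, p=float(p), q=float(q)))
    return out


# --------------------------------------------------------------------------
# Correlation


def pearson_correlation(
    pred_ages: Mapping[str, Optional[float]],
    gold_ages: Mapping[str, Optional[float]],
) -> CorrelationResult:
    """Pearson r over instances where both values are present.

    Requires at least 3 complete pairs; zero variance in either vector →
    undefined (None), reported with the pair count.
    """
    keys = [
        k
        for k in gold_ages
        if gold_ages[k] is not None and pred_ages.get(k) is not None
    ]
    n = len(keys)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    x = np.array([pred_ages[k] for k in keys], dtype=float)
    y = np.array([gold_ages[k] for k in keys], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(r=None, n=n)
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationResult(r=r, n=n)
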