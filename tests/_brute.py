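"""Independent brute-force oracles used to cross-check the evaluation code
and the generator's gold files.  Everything here is written from the
definitions directly (dict counting, literal formulas), deliberately sharing
no code with the package."""

import math


def brute_confusion(pred_pairs, gold_pairs, positive):
    pred = dict(pred_pairs)
    tp = fp = fn = tn = 0
    for key, g in gold_pairs:
        p = pred.get(key)
        gold_pos = g == positive
        pred_pos = p == positive if p is not None else False
        if p is None:
            if gold_pos:
                fn += 1
            else:
                tn += 1
        elif pred_pos and gold_pos:
            tp += 1
        elif pred_pos:
            fp += 1
        elif gold_pos:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def brute_metrics(tp, fp, fn, tn):
    recall = tp / (tp + fn) if (tp + fn) else None
    precision = tp / (tp + fp) if (tp + fp) else None
    specificity = tn / (tn + fp) if (tn + fp) else None
    if recall is None or precision is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return recall, precision, specificity, f1


def brute_age_confusion(pred, gold, tol=1.0):
    tp = fp = fn = tn = 0
    for key, g in gold.items():
        p = pred.get(key)
        if p is None and g is None:
            tn += 1
        elif p is None:
            fn += 1
        elif g is None or abs(p - g) > tol:
            fp += 1
        else:
            tp += 1
    return tp, fp, fn, tn


def brute_kappa(a, b):
    """(kappa, p_o, p_e, se) from the literal formulas; kappa None if p_e=1."""
    n = len(a)
    cats = sorted(set(a) | set(b), key=repr)
    p_o = sum(1 for x, y in zip(a, b) if x == y) / n
    p_e = 0.0
    for c in cats:
        p_e += (sum(1 for x in a if x == c) / n) * (sum(1 for y in b if y == c) / n)
    if abs(p_e - 1.0) < 1e-15:
        return None, p_o, p_e, None
    kappa = (p_o - p_e) / (1 - p_e)
    se = math.sqrt(p_o * (1 - p_o) / (n * (1 - p_e) ** 2))
    return kappa, p_o, p_e, se


def brute_pearson(xs, ys):
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    if sxx == 0 or syy == 0:
        return None
    return sxy / math.sqrt(sxx * syy)


def recount_note_gold(sentence_labels):
    """Note-level gold recomputed by naive counting over sentence gold."""
    by_note = {}
    for s in sentence_labels:
        by_note.setdefault(s.note_id, []).append(s)
    out = {}
    for nid, sents in by_note.items():
        classes = [c for s in sents for c in s.behavior_evidence]
        if "B3" in classes:
            behavior = "B3"
        elif "B2" in classes:
            behavior = "B2"
        else:
            behavior = "B1"
        out[nid] = (behavior, any(s.perianal for s in sents))
    return out


def recount_patient_gold(note_gold, note_to_patient):
    """Patient-level gold recomputed from note gold by naive max/any."""
    by_patient = {}
    for nid, (behavior, peri) in note_gold.items():
        by_patient.setdefault(note_to_patient[nid], []).append((behavior, peri))
    rank = {"B1": 1, "B2": 2, "B3": 3}
    return {
        pid: (
            max((b for b, _ in rows), key=rank.get),
            any(p for _, p in rows),
        )
        for pid, rows in by_patient.items()
    }
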