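import math
import random

import pytest

from cdpheno.evaluate import (
    ConfusionCounts,
    age_confusion,
    class_metrics,
    cohens_kappa,
    compare_kappas,
    confusion_counts,
    pearson_correlation,
)
from _brute import (
    brute_age_confusion,
    brute_confusion,
    brute_kappa,
    brute_metrics,
    brute_pearson,
)


class TestConfusionCounts:
    def test_perfect_prediction(self):
        gold = [(f"i{k}", "pos" if k < 4 else "neg") for k in range(10)]
        c = confusion_counts(gold, gold, "pos")
        assert (c.tp, c.fp, c.fn, c.tn) == (4, 0, 0, 6)

    def test_mixed_prediction_matches_manual_count(self):
        # 12 gold positive / 8 negative; the labeler flags 10, 8 correctly
        gold = [(f"i{k}", "pos" if k < 12 else "neg") for k in range(20)]
        pred_pos = list(range(8)) + [12, 13]  # 8 true + 2 false positives
        pred = [(f"i{k}", "pos" if k in pred_pos else "neg") for k in range(20)]
        c = confusion_counts(pred, gold, "pos")
        assert (c.tp, c.fp, c.fn, c.tn) == (8, 2, 4, 6)

    def test_empty_inputs(self):
        c = confusion_counts([], [], "pos")
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 0, 0)

    def test_missing_prediction_is_fn_or_tn(self):
        gold = [("a", "pos"), ("b", "neg")]
        c = confusion_counts([], gold, "pos")
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 1, 1)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            confusion_counts([("a", "pos"), ("a", "neg")], [("a", "pos")], "pos")


class TestClassMetrics:
    def test_perfect(self):
        m = class_metrics(ConfusionCounts(5, 0, 0, 5))
        assert (m.recall, m.precision, m.specificity, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_formula_values(self):
        m = class_metrics(ConfusionCounts(8, 2, 4, 6))
        assert m.recall == pytest.approx(8 / 12)
        assert m.precision == pytest.approx(0.8)
        assert m.specificity == pytest.approx(0.75)
        assert m.f1 == pytest.approx(2 * 0.8 * (8 / 12) / (0.8 + 8 / 12))

    def test_degenerate_counts_undefined_not_zero(self):
        m = class_metrics(ConfusionCounts(0, 0, 0, 10))
        assert m.recall is None and m.precision is None
        assert m.specificity == 1.0 and m.f1 is None


class TestAgeConfusion:
    def test_four_case_contract(self):
        pred = {"a": 26.0, "b": 28.0, "c": None, "d": None}
        gold = {"a": 25.0, "b": 25.0, "c": 25.0, "d": None}
        c = age_confusion(pred, gold)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_wrong_value_is_fp_only_never_fn(self):
        c = age_confusion({"a": 30.0}, {"a": 25.0})
        assert (c.fp, c.fn) == (1, 0)

    def test_value_where_gold_absent_is_fp(self):
        c = age_confusion({"a": 30.0}, {"a": None})
        assert c.fp == 1

    def test_zero_tolerance_reduces_to_exact_match(self):
        rng = random.Random(7)
        pred = {str(i): float(rng.randint(10, 15)) for i in range(50)}
        gold = {str(i): float(rng.randint(10, 15)) for i in range(50)}
        c = age_confusion(pred, gold, tolerance=0)
        # every instance has both values → TP iff exactly equal, else FP
        assert c.tp == sum(pred[k] == gold[k] for k in gold)
        assert c.fp == 50 - c.tp and c.fn == 0 and c.tn == 0


class TestCohensKappa:
    def test_identical_labelings(self):
        labels = ["x", "y", "x", "z", "y", "x"]
        res = cohens_kappa(labels, labels)
        assert res.kappa == pytest.approx(1.0)

    def test_hand_computed_2x2_table(self):
        # agreement table a=4, b=1, c=1, d=4 → p_o=0.8, p_e=0.5, kappa=0.6
        a = ["+"] * 5 + ["-"] * 5
        b = ["+"] * 4 + ["-"] + ["+"] + ["-"] * 4
        res = cohens_kappa(a, b)
        assert res.p_observed == pytest.approx(0.8)
        assert res.p_expected == pytest.approx(0.5)
        assert res.kappa == pytest.approx(0.6)
        assert res.se == pytest.approx(math.sqrt(0.8 * 0.2 / (10 * 0.25)))

    def test_relabeling_invariance(self):
        rng = random.Random(3)
        a = [rng.choice("xyz") for _ in range(200)]
        b = [rng.choice("xyz") for _ in range(200)]
        mapping = {"x": "u", "y": "v", "z": "w"}
        k1 = cohens_kappa(a, b).kappa
        k2 = cohens_kappa([mapping[v] for v in a], [mapping[v] for v in b]).kappa
        assert k1 == pytest.approx(k2)

    def test_constant_equal_raters_undefined(self):
        res = cohens_kappa(["x"] * 10, ["x"] * 10)
        assert res.kappa is None and res.se is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            cohens_kappa(["x"], ["x", "y"])

    def test_independent_labelings_near_zero(self):
        rng = random.Random(12)
        n = 10_000
        a = [rng.choice("pq") for _ in range(n)]
        b = [rng.choice("pq") for _ in range(n)]
        res = cohens_kappa(a, b)
        assert abs(res.kappa) <= 3 * res.se


class TestCompareKappas:
    def test_equal_kappas_give_z0_p1(self):
        r = cohens_kappa(["x", "y"] * 10, ["x", "y"] * 8 + ["y", "x"] * 2)
        (cmp_,) = compare_kappas([r, r], [(0, 1)])
        assert cmp_.z == 0.0 and cmp_.p == pytest.approx(1.0)
        assert cmp_.q == pytest.approx(cmp_.p)  # BH with m=1 is the identity

    def test_z_and_p_formula(self):
        from dataclasses import replace

        base = cohens_kappa(["x", "y"] * 10, ["x", "y"] * 10)
        r1 = replace(base, kappa=0.9, se=0.03)
        r2 = replace(base, kappa=0.8, se=0.04)
        (cmp_,) = compare_kappas([r1, r2], [(0, 1)])
        assert cmp_.z == pytest.approx(2.0)
        assert cmp_.p == pytest.approx(0.0455, abs=1e-4)

    def test_bh_ordering_over_multiple_pairs(self):
        from dataclasses import replace

        base = cohens_kappa(["x", "y"] * 10, ["x", "y"] * 10)
        rs = [replace(base, kappa=k, se=0.05) for k in (0.9, 0.8, 0.5)]
        out = compare_kappas(rs, [(0, 1), (0, 2), (1, 2)])
        assert all(c.q >= c.p for c in out)

    def test_zero_ses_rejected(self):
        from dataclasses import replace

        base = cohens_kappa(["x", "y"] * 10, ["x", "y"] * 10)
        r = replace(base, kappa=0.5, se=0.0)
        with pytest.raises(ValueError, match="zero"):
            compare_kappas([r, r], [(0, 1)])


class TestPearsonCorrelation:
    def test_identity_and_shift_invariance(self):
        gold = {str(i): float(i) for i in range(10)}
        assert pearson_correlation(gold, gold).r == pytest.approx(1.0)
        shifted = {k: v + 1 for k, v in gold.items()}
        assert pearson_correlation(shifted, gold).r == pytest.approx(1.0)

    def test_brute_force_value(self):
        pred = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0, "e": 5.0}
        gold = {"a": 2.0, "b": 1.0, "c": 3.0, "d": 4.0, "e": 5.0}
        res = pearson_correlation(pred, gold)
        assert res.r == pytest.approx(
            brute_pearson(list(pred.values()), list(gold.values()))
        )
        assert res.n == 5

    def test_incomplete_pairs_excluded(self):
        pred = {"a": 1.0, "b": None, "c": 3.0, "d": 4.0, "e": 5.0}
        gold = {"a": 1.0, "b": 2.0, "c": 3.0, "d": None, "e": 5.0}
        assert pearson_correlation(pred, gold).n == 3

    def test_zero_variance_undefined(self):
        pred = {"a": 2.0, "b": 2.0, "c": 2.0}
        gold = {"a": 1.0, "b": 2.0, "c": 3.0}
        assert pearson_correlation(pred, gold).r is None

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3"):
            pearson_correlation({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})


class TestOracleEquivalenceSpotChecks:
    """Randomized agreement with the brute-force oracles (a handful of
    seeds here; the acceptance suite sweeps 200 corpora)."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_confusion_and_kappa_match_brute_force(self, seed):
        rng = random.Random(seed)
        n = rng.randint(50, 200)
        ids = [f"i{k}" for k in range(n)]
        gold = [(i, rng.choice(["pos", "neg"])) for i in ids]
        pred = [(i, rng.choice(["pos", "neg"])) for i in ids if rng.random() < 0.9]
        c = confusion_counts(pred, gold, "pos")
        assert (c.tp, c.fp, c.fn, c.tn) == brute_confusion(pred, gold, "pos")
        m = class_metrics(c)
        br, bp, bs, bf = brute_metrics(c.tp, c.fp, c.fn, c.tn)
        for got, want in ((m.recall, br), (m.precision, bp), (m.specificity, bs), (m.f1, bf)):
            assert (got is None and want is None) or abs(got - want) < 1e-12

        a = [rng.choice("xy") for _ in range(n)]
        b = [rng.choice("xy") for _ in range(n)]
        res = cohens_kappa(a, b)
        bk, bpo, bpe, bse = brute_kappa(a, b)
        assert abs(res.kappa - bk) < 1e-12
        assert abs(res.se - bse) < 1e-12

        ages_p = {i: (rng.uniform(10, 50) if rng.random() < 0.7 else None) for i in ids}
        ages_g = {i: (rng.uniform(10, 50) if rng.random() < 0.7 else None) for i in ids}
        c2 = age_confusion(ages_p, ages_g)
        assert (c2.tp, c2.fp, c2.fn, c2.tn) == brute_age_confusion(ages_p, ages_g)
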