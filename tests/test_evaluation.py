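"""Metric tests against independent oracles.

AUROC is cross-checked with an exhaustive pairwise-concordance count
(Mann-Whitney with half credit for ties) and AUPR with a step-area
enumeration over threshold cuts; both oracles are plain re-derivations
independent of the curve-based implementation.
"""

import numpy as np
import pytest

from grnfusion.data_io import GeneIndex, GoldStandard, RankedEdgeList
from grnfusion.evaluation import (ConfusionCounts, aupr, auroc, confusion_rates,
                                  early_precision_ratio, edge_universe, evaluate,
                                  overall_score)


def concordance_auroc(labels, scores):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def step_aupr(labels, scores):
    """Sweep distinct thresholds descending; precision held per recall step."""
    order = np.argsort(-np.asarray(scores, float), kind="stable")
    labels = np.asarray(labels)[order]
    scores = np.asarray(scores, float)[order]
    k = labels.sum()
    area, prev_recall = 0.0, 0.0
    tp = fp = 0
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and scores[j] == scores[i]:
            j += 1
        tp += labels[i:j].sum()
        fp += (j - i) - labels[i:j].sum()
        recall = tp / k
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


def ranking_from(labels, scores, n_genes=None):
    """Wrap label/score vectors as edges of a synthetic gene universe."""
    n = len(labels)
    genes = GeneIndex(tuple(f"g{i}" for i in range(n + 1)))
    edges = [(f"g{i}", f"g{n}", float(s)) for i, s in enumerate(scores)]
    gold = GoldStandard(frozenset((f"g{i}", f"g{n}") for i, l in enumerate(labels) if l))
    universe = [(f"g{i}", f"g{n}") for i in range(n)]
    return RankedEdgeList(edges), gold, universe


class TestConfusionRates:
    def test_arithmetic(self):
        r = confusion_rates(ConfusionCounts(TP=6, FP=9, FN=9, TN=66))
        assert r["recall"] == pytest.approx(0.4)
        assert r["precision"] == pytest.approx(0.4)
        assert r["tpr"] == r["recall"]
        assert r["fpr"] == pytest.approx(9 / 75)

    def test_zero_denominator_flagged(self):
        r = confusion_rates(ConfusionCounts(TP=0, FP=0, FN=3, TN=5))
        assert r["precision"] == 0.0 and "precision" in r["undefined"]

    def test_everything_positive_gives_full_recall(self):
        r = confusion_rates(ConfusionCounts(TP=4, FP=6, FN=0, TN=0))
        assert r["recall"] == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(TP=-1, FP=0, FN=0, TN=0)


class TestAuroc:
    def test_four_edge_toy_is_three_quarters(self):
        ranked, gold, universe = ranking_from([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1])
        assert auroc(ranked, gold, universe) == pytest.approx(0.75)

    def test_perfect_and_reversed_rankings(self):
        ranked, gold, universe = ranking_from([1, 1, 0, 0], [4, 3, 2, 1])
        assert auroc(ranked, gold, universe) == 1.0
        rev, _, _ = ranking_from([1, 1, 0, 0], [1, 2, 3, 4])
        assert auroc(rev, gold, universe) == 0.0

    def test_all_tied_scores_give_half(self):
        ranked, gold, universe = ranking_from([1, 0, 1, 0], [0.5] * 4)
        assert auroc(ranked, gold, universe) == pytest.approx(0.5)

    def test_equals_pair_concordance_on_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            labels = (rng.uniform(size=n) < 0.3).astype(int)
            if labels.sum() in (0, n):
                labels[0], labels[1] = 1, 0
            scores = np.round(rng.uniform(size=n), 2)  # induce ties
            ranked, gold, universe = ranking_from(labels, scores)
            assert auroc(ranked, gold, universe) == pytest.approx(
                concordance_auroc(labels, scores), abs=1e-12)

    def test_ranking_plus_reversal_sums_to_one(self, rng):
        labels = (rng.uniform(size=30) < 0.4).astype(int)
        labels[0], labels[1] = 1, 0
        scores = rng.uniform(size=30)  # continuous, no ties
        fwd, gold, universe = ranking_from(labels, scores)
        rev, _, _ = ranking_from(labels, 1 - scores)
        assert auroc(fwd, gold, universe) + auroc(rev, gold, universe) == pytest.approx(1.0)

    def test_no_positive_edges_rejected(self):
        ranked, _, universe = ranking_from([1, 0], [1.0, 0.5])
        empty_gold_errs = (ValueError,)
        with pytest.raises(empty_gold_errs):
            auroc(ranked, GoldStandard(frozenset({("x", "y")})), universe)


class TestAupr:
    def test_perfect_ranking_is_one(self):
        ranked, gold, universe = ranking_from([1, 1, 0], [3, 2, 1])
        assert aupr(ranked, gold, universe) == 1.0

    def test_four_edge_toy_step_area(self):
        labels, scores = [1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]
        ranked, gold, universe = ranking_from(labels, scores)
        expected = step_aupr(labels, scores)
        assert expected == pytest.approx(1 / 2 + 1 / 3)  # frozen oracle value
        assert aupr(ranked, gold, universe) == pytest.approx(expected, abs=1e-12)

    def test_equals_step_oracle_on_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 50))
            labels = (rng.uniform(size=n) < 0.3).astype(int)
            if labels.sum() in (0, n):
                labels[0], labels[1] = 1, 0
            scores = np.round(rng.uniform(size=n), 2)
            ranked, gold, universe = ranking_from(labels, scores)
            assert aupr(ranked, gold, universe) == pytest.approx(
                step_aupr(labels, scores), abs=1e-12)

    def test_random_scores_approach_prevalence(self, rng):
        n, prev = 4000, 0.2
        labels = (rng.uniform(size=n) < prev).astype(int)
        scores = rng.uniform(size=n)
        ranked, gold, universe = ranking_from(labels, scores)
        assert aupr(ranked, gold, universe) == pytest.approx(labels.mean(), abs=0.05)


class TestOverallScore:
    @pytest.mark.parametrize("a,p,expected", [(0.8, 0.4, 0.6), (1, 1, 1), (0, 0, 0)])
    def test_arithmetic_mean(self, a, p, expected):
        assert overall_score(a, p) == pytest.approx(expected)


class TestEarlyPrecision:
    def _instance(self, n_genes, k, tps_in_top):
        """Gold with k positives; ranking placing tps_in_top of them on top."""
        genes = GeneIndex(tuple(f"g{i}" for i in range(n_genes)))
        universe = edge_universe(genes)
        gold_edges = universe[:k]
        ranked_top = gold_edges[:tps_in_top] + universe[k:k + (k - tps_in_top)]
        rest = [e for e in universe if e not in ranked_top]
        scored = [(r, t, float(len(universe) - i))
                  for i, (r, t) in enumerate(ranked_top + rest)]
        return RankedEdgeList(scored), GoldStandard(frozenset(gold_edges)), genes

    def test_toy_epr(self):
        ranked, gold, genes = self._instance(10, 15, 6)
        ep, epr = early_precision_ratio(ranked, gold, len(genes))
        assert ep == pytest.approx(0.4)
        assert epr == pytest.approx(2.4)

    def test_perfect_topk_maximal_epr(self):
        ranked, gold, genes = self._instance(10, 15, 15)
        ep, epr = early_precision_ratio(ranked, gold, len(genes))
        assert ep == 1.0 and epr == pytest.approx(90 / 15)

    def test_invariant_to_score_rescaling(self):
        ranked, gold, genes = self._instance(8, 10, 4)
        scaled = RankedEdgeList([(r, t, s * 17.3) for r, t, s in ranked])
        assert early_precision_ratio(ranked, gold, 8) == \
            early_precision_ratio(scaled, gold, 8)

    def test_permutation_null_mean_near_one(self, rng):
        genes = GeneIndex(tuple(f"g{i}" for i in range(10)))
        universe = edge_universe(genes)
        gold = GoldStandard(frozenset(universe[:15]))
        k, n_edges, reps = 15, len(universe), 10_000
        eprs = np.empty(reps)
        pos = np.zeros(n_edges, bool)
        pos[:15] = True
        for i in range(reps):
            perm = rng.permutation(n_edges)
            tps = pos[perm[:k]].sum()
            eprs[i] = (tps / k) / (k / 90)
        se = eprs.std(ddof=1) / np.sqrt(reps)
        assert abs(eprs.mean() - 1.0) < 3 * se + 1e-12

    def test_empty_gold_rejected(self):
        ranked, _, genes = self._instance(6, 5, 2)
        with pytest.raises(ValueError):
            early_precision_ratio(ranked, GoldStandard(frozenset()), 6)


class TestEvaluate:
    def test_perfect_predictor_maxes_every_metric(self):
        genes = GeneIndex(("a", "b", "c"))
        universe = edge_universe(genes)
        gold = GoldStandard(frozenset(universe[:2]))
        scored = [(r, t, 6.0 - i) for i, (r, t) in enumerate(universe)]
        report = evaluate(RankedEdgeList(scored), gold, genes)
        assert report.auroc == 1.0 and report.aupr == 1.0 and report.overall == 1.0
        assert report.epr == pytest.approx(6 / 2)

    def test_missing_edges_appended_at_zero(self):
        genes = GeneIndex(("a", "b", "c"))
        gold = GoldStandard(frozenset({("a", "b")}))
        # the ranking covers a single edge; the other five enter at score 0
        report = evaluate(RankedEdgeList([("a", "b", 0.9)]), gold, genes)
        assert report.n_universe == 6
        assert report.auroc == 1.0

    def test_report_serializes_to_json(self, tmp_path):
        genes = GeneIndex(("a", "b", "c"))
        gold = GoldStandard(frozenset({("a", "b")}))
        report = evaluate(RankedEdgeList([("a", "b", 0.9)]), gold, genes,
                          with_curves=True)
        import json
        payload = json.loads(report.to_json(tmp_path / "m.json"))
        assert payload["overall"] == pytest.approx((payload["auroc"] + payload["aupr"]) / 2)
        assert payload["roc_points"]
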