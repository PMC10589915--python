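"""Ranked-edge evaluation against a gold standard.

The evaluated universe is every ordered non-self gene pair (restricted to
TF -> any when a transcription-factor list defines the task).  Gold
positives are the label-1 edges; every other universe edge is treated as a
negative (the DREAM convention) unless strict mode confines scoring to
explicitly labeled pairs.  Edges the ranking omits are appended with score 0
under the global tie-break, so every curve sweeps the full universe.

Metrics:

* ``recall = TPR = TP / (TP + FN)``, ``precision = TP / (TP + FP)``,
  ``FPR = FP / (FP + TN)``;
* AUROC — trapezoidal area under the ROC curve with equal scores grouped
  into one threshold step (equivalently the Mann-Whitney concordance
  probability with half credit for ties);
* AUPR — area under the precision-recall step curve (precision held across
  each recall increment; no trapezoidal interpolation, which over-credits);
* overall score = (AUROC + AUPR) / 2;
* EP / EPR — early precision: the fraction of true positives among the top
  k ranked edges, k being the number of gold positives, and its ratio to
  the random-predictor baseline k / (n * (n - 1)) for n genes.

All metrics depend only on the edge ordering, never on score magnitudes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_auc_score, roc_curve

from .data_io import GeneIndex, GoldStandard, RankedEdgeList

__all__ = ["ConfusionCounts", "MetricReport", "confusion_rates", "edge_universe",
           "auroc", "aupr", "overall_score", "early_precision_ratio", "evaluate"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion_rates(c: ConfusionCounts) -> dict:
    """Recall (= TPR), precision and FPR; zero denominators give a flagged 0."""
    flags = []

    def ratio(num, den, name):
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    recall = ratio(c.TP, c.TP + c.FN, "recall")
    precision = ratio(c.TP, c.TP + c.FP, "precision")
    fpr = ratio(c.FP, c.FP + c.TN, "fpr")
    return {"recall": recall, "precision": precision, "tpr": recall, "fpr": fpr,
            "undefined": tuple(flags)}


def edge_universe(genes: GeneIndex, tf_names=None) -> list[tuple[str, str]]:
    """All ordered non-self pairs; regulators restricted to TFs when given."""
    regs = list(genes.names) if tf_names is None else list(tf_names)
    return [(r, t) for r in regs for t in genes.names if r != t]


def _complete_ranking(ranked: RankedEdgeList, universe: list[tuple[str, str]]) -> list[tuple[str, str, float]]:
    """Universe edges in ranked order, unscored edges appended at score 0."""
    scores = {(r, t): s for r, t, s in ranked}
    completed = [(r, t, scores.get((r, t), 0.0)) for r, t in universe]
    completed.sort(key=lambda e: (-e[2], e[0], e[1]))
    return completed


def _labels_scores(ranked: RankedEdgeList, gold: GoldStandard,
                   universe: list[tuple[str, str]], strict_negatives: bool):
    completed = _complete_ranking(ranked, universe)
    if strict_negatives:
        labeled = gold.positive_edges | gold.known_negative_edges
        completed = [e for e in completed if (e[0], e[1]) in labeled]
    labels = np.array([1 if (r, t) in gold.positive_edges else 0 for r, t, _ in completed])
    scores = np.array([s for _, _, s in completed])
    if labels.sum() == 0:
        raise ValueError("no gold positives in the evaluated universe")
    if labels.sum() == len(labels):
        raise ValueError("no negatives in the evaluated universe")
    return completed, labels, scores


def auroc(ranked: RankedEdgeList, gold: GoldStandard, universe,
          strict_negatives: bool = False) -> float:
    """Area under the ROC curve of the completed ranking over the universe."""
    _, labels, scores = _labels_scores(ranked, gold, universe, strict_negatives)
    return float(roc_auc_score(labels, scores))


def aupr(ranked: RankedEdgeList, gold: GoldStandard, universe,
         strict_negatives: bool = False) -> float:
    """Area under the precision-recall step curve (average precision)."""
    _, labels, scores = _labels_scores(ranked, gold, universe, strict_negatives)
    return float(average_precision_score(labels, scores))


def overall_score(auroc_value: float, aupr_value: float) -> float:
    """Arithmetic mean of AUROC and AUPR."""
    return (auroc_value + aupr_value) / 2.0


def early_precision_ratio(ranked: RankedEdgeList, gold: GoldStandard,
                          n_genes: int, universe=None,
                          tf_density: int | None = None) -> tuple[float, float]:
    """Early precision among the top-k edges and its ratio to chance.

    k is the number of gold positives.  The chance baseline is the edge
    density k / (n * (n - 1)); for TF-restricted tasks ``tf_density`` (the
    number of TFs) switches the denominator to ``|TF| * (n - 1)``.
    """
    k = gold.n_positives
    if k == 0:
        raise ValueError("gold standard has no positive edges")
    if universe is None:
        ordered = list(ranked)
    else:
        ordered = _complete_ranking(ranked, universe)
    if len(ordered) < k:
        raise ValueError(f"ranking covers {len(ordered)} edges; need at least k={k}")
    top = ordered[:k]
    tps = sum(1 for r, t, _ in top if (r, t) in gold.positive_edges)
    ep = tps / k
    n_pairs = (tf_density * (n_genes - 1)) if tf_density else n_genes * (n_genes - 1)
    density = k / n_pairs
    return ep, ep / density


@dataclass
class MetricReport:
    """All evaluation statistics for one ranking, JSON-serializable."""

    auroc: float
    aupr: float
    overall: float
    ep: float
    epr: float
    n_genes: int
    n_positives: int
    n_universe: int
    roc_points: list = field(default_factory=list, repr=False)
    pr_points: list = field(default_factory=list, repr=False)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "wt", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def evaluate(ranked: RankedEdgeList, gold: GoldStandard, genes: GeneIndex,
             tf_names=None, strict_negatives: bool = False,
             with_curves: bool = False) -> MetricReport:
    """Full metric report for one ranking against one gold standard."""
    universe = edge_universe(genes, tf_names)
    _, labels, scores = _labels_scores(ranked, gold, universe, strict_negatives)
    auroc_v = float(roc_auc_score(labels, scores))
    aupr_v = float(average_precision_score(labels, scores))
    ep, epr = early_precision_ratio(ranked, gold, len(genes), universe=universe)
    roc_pts, pr_pts = [], []
    if with_curves:
        fpr, tpr, _ = roc_curve(labels, scores)
        roc_pts = np.column_stack([fpr, tpr]).tolist()
        prec, rec, _ = precision_recall_curve(labels, scores)
        pr_pts = np.column_stack([rec, prec]).tolist()
    return MetricReport(
        auroc=auroc_v, aupr=aupr_v, overall=overall_score(auroc_v, aupr_v),
        ep=ep, epr=epr, n_genes=len(genes), n_positives=gold.n_positives,
        n_universe=len(universe), roc_points=roc_pts, pr_points=pr_pts,
    )
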