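"""End-to-end inference orchestration and cross-validated parameter search.

``infer_network`` chains the stages: pairwise MIC on pooled expression ->
per-target regulator pruning -> ODE design matrices -> dual tree-ensemble
fits with multiplicative importance fusion -> a globally ranked directed
edge list.

``grid_search_cv`` implements supervised model selection: target genes are
split into two folds; on the training fold every (MIC threshold, boosting
learning rate) grid cell is scored against the gold edges pointing into
training-fold targets, the best cell is applied to the held-out fold, the
folds are swapped and the two held-out scores are averaged.  Edges are
attributed to folds by their *target* gene, matching the per-target model
structure.  The MIC matrix and the forest fits (which do not depend on the
learning rate) are cached across grid cells.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from .data_io import ExpressionDataset, GoldStandard, RankedEdgeList, write_ranked_edges
from .evaluation import evaluate, overall_score
from .fusion import (EnsembleConfig, ImportanceMatrix, build_importance_matrices,
                     fit_importances, fuse_scores, rank_edges)
from .mic import MicConfig, MicMatrix, mic_matrix
from .ode_design import OdeConfig, assemble_design
from .regulators import build_regulator_sets, select_regulators

__all__ = ["PipelineConfig", "infer_network", "grid_search_cv", "CvResult",
           "default_threshold_grid", "default_learning_rate_grid"]

log = logging.getLogger("grnfusion")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs, serializable to/from YAML."""

    mic_threshold: float = 0.15
    mic: MicConfig = field(default_factory=MicConfig)
    ode: OdeConfig = field(default_factory=OdeConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    mode: str = "fused"
    normalize: bool = True
    min_regulators: int = 3

    def to_yaml(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        text = yaml.safe_dump(payload, sort_keys=True)
        if path is not None:
            with open(path, "wt", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        for key, sub in (("mic", MicConfig), ("ode", OdeConfig), ("ensemble", EnsembleConfig)):
            if key in payload and isinstance(payload[key], dict):
                payload[key] = sub(**payload[key])
        return cls(**payload)


def default_threshold_grid(profile: str = "simulated", n: int = 30) -> np.ndarray:
    """MIC threshold grids: a tight band near 0.15 for dense simulated data,
    a wide band for sparse real data whose MIC distribution is broader."""
    if profile == "simulated":
        return np.linspace(0.1, 0.2, n)
    if profile == "real":
        return np.linspace(0.2, 0.7, n)
    raise ValueError(f"unknown profile {profile!r}")


def default_learning_rate_grid(n: int = 10) -> np.ndarray:
    return np.geomspace(0.01, 0.3, n)


def infer_network(dataset: ExpressionDataset, cfg: PipelineConfig | None = None,
                  mic: MicMatrix | None = None,
                  targets=None) -> tuple[RankedEdgeList, ImportanceMatrix]:
    """Run the full inference chain on one dataset.

    ``mic`` may be a precomputed matrix (the expensive stage); ``targets``
    restricts modeling to a gene subset, leaving other columns zero — used
    by cross-validation, where only training-fold targets may be modeled.
    """
    cfg = cfg or PipelineConfig()
    t0 = time.perf_counter()
    if mic is None:
        mic = mic_matrix(dataset, candidate_regulators=dataset.tf_names, config=cfg.mic)
        log.info("MIC matrix: %d genes, pooled N=%d (%.2fs)", len(dataset.genes),
                 dataset.pooled_matrix().shape[0], time.perf_counter() - t0)
    target_list = list(targets) if targets is not None else list(dataset.genes.names)
    reg_sets = build_regulator_sets(mic, dataset, cfg.mic_threshold,
                                    min_regulators=cfg.min_regulators)
    reg_sets.by_target = {t: reg_sets.by_target[t] for t in target_list}
    sizes = [len(v) for v in reg_sets.by_target.values()]
    log.info("regulator sets: mean |R_j|=%.1f over %d targets at T_MIC=%.3f",
             float(np.mean(sizes)), len(sizes), cfg.mic_threshold)
    mats = build_importance_matrices(
        dataset, reg_sets, cfg.ode, cfg.ensemble,
        modes=(cfg.mode,), normalize=cfg.normalize)
    w = mats[cfg.mode]
    ranked = rank_edges(w)
    log.info("ranked %d edges (%.2fs total)", len(ranked), time.perf_counter() - t0)
    return ranked, w


@dataclass
class CvResult:
    """Outcome of the 2-fold gene-wise grid search."""

    best_by_fold: list[dict]
    mean_test_overall: float
    score_table: list[dict]                 # one row per (fold, threshold, lr)
    folds: list[list[str]]


def _fold_gold(gold: GoldStandard, fold_targets: set[str]) -> GoldStandard:
    return GoldStandard(
        frozenset(e for e in gold.positive_edges if e[1] in fold_targets),
        frozenset(e for e in gold.known_negative_edges if e[1] in fold_targets),
    )


def _fold_universe(genes, tf_names, fold_targets: set[str]):
    regs = list(genes.names) if tf_names is None else list(tf_names)
    return [(r, t) for r in regs for t in genes.names if t in fold_targets and r != t]


def _score_fold(dataset, mic, gold, targets, threshold, learning_rate, base_cfg,
                caches, observer=None):
    """Overall score of one grid cell on one target fold, with caching."""
    from sklearn.metrics import average_precision_score, roc_auc_score

    genes = dataset.genes
    fold_targets = set(targets)
    reg_cache, design_cache, forest_cache, boosted_cache = caches
    ens = base_cfg.ensemble
    G = len(genes)
    w = np.zeros((G, G))
    for target in targets:
        if observer is not None:
            observer(target)
        key_r = (threshold, target)
        if key_r not in reg_cache:
            reg_cache[key_r] = select_regulators(
                mic, target, threshold, tf_restriction=dataset.tf_names,
                min_regulators=base_cfg.min_regulators)
        regs = reg_cache[key_r]
        key_d = (tuple(regs), target)
        if key_d not in design_cache:
            design_cache[key_d] = assemble_design(dataset, target, regs, base_cfg.ode)
        design = design_cache[key_d]
        if key_d not in forest_cache:
            forest_cache[key_d] = fit_importances(design, "forest", ens)
        key_b = (tuple(regs), target, learning_rate)
        if key_b not in boosted_cache:
            cfg_b = dataclasses.replace(ens, learning_rate=float(learning_rate))
            boosted_cache[key_b] = fit_importances(design, "boosted", cfg_b)
        vec = fuse_scores(boosted_cache[key_b], forest_cache[key_d])
        if base_cfg.normalize and vec.sum() > 0:
            vec = vec / vec.sum()
        rows = [genes.index_of(r) for r in regs]
        w[rows, genes.index_of(target)] = vec
    universe = _fold_universe(genes, dataset.tf_names, fold_targets)
    fold_gold = _fold_gold(gold, fold_targets)
    labels = np.array([1 if e in fold_gold.positive_edges else 0 for e in universe])
    scores = np.array([w[genes.index_of(r), genes.index_of(t)] for r, t in universe])
    auroc_v = float(roc_auc_score(labels, scores))
    aupr_v = float(average_precision_score(labels, scores))
    return overall_score(auroc_v, aupr_v)


def grid_search_cv(dataset: ExpressionDataset, gold: GoldStandard,
                   thresholds, learning_rates, n_folds: int = 2, seed: int = 0,
                   base_cfg: PipelineConfig | None = None,
                   mic: MicMatrix | None = None,
                   observer=None) -> CvResult:
    """2-fold gene-wise grid search over MIC threshold x boosting learning rate.

    ``observer(stage, fold_index, target)`` (optional) is called for every
    target whose model is fit, tagged with the stage (``"select"`` or
    ``"test"``) — instrumentation for leakage auditing.
    """
    if n_folds != 2:
        raise ValueError("the protocol is defined for 2 folds")
    base_cfg = base_cfg or PipelineConfig()
    thresholds = list(thresholds)
    learning_rates = list(learning_rates)
    if not thresholds or not learning_rates:
        raise ValueError("grids must be non-empty")
    rng = np.random.default_rng(seed)
    names = list(dataset.genes.names)
    perm = rng.permutation(len(names))
    half = len(names) // 2
    folds = [sorted(names[i] for i in perm[:half]), sorted(names[i] for i in perm[half:])]
    for f, fold in enumerate(folds):
        if not any(e[1] in set(fold) for e in gold.positive_edges):
            raise ValueError(f"fold {f} holds no gold positives; try a different seed")
    if mic is None:
        mic = mic_matrix(dataset, candidate_regulators=dataset.tf_names,
                         config=base_cfg.mic)
    caches = ({}, {}, {}, {})
    table = []
    best_by_fold = []
    test_scores = []
    for train_idx in range(2):
        train, test = folds[train_idx], folds[1 - train_idx]
        best = None
        for th in thresholds:
            for lr in learning_rates:
                obs = (lambda t: observer("select", train_idx, t)) if observer else None
                score = _score_fold(dataset, mic, gold, train, float(th), float(lr),
                                    base_cfg, caches, observer=obs)
                table.append({"train_fold": train_idx, "threshold": float(th),
                              "learning_rate": float(lr), "train_overall": score})
                if best is None or score > best["train_overall"]:
                    best = {"train_fold": train_idx, "threshold": float(th),
                            "learning_rate": float(lr), "train_overall": score}
        obs = (lambda t: observer("test", train_idx, t)) if observer else None
        test_score = _score_fold(dataset, mic, gold, test, best["threshold"],
                                 best["learning_rate"], base_cfg, caches, observer=obs)
        best["test_overall"] = test_score
        best_by_fold.append(best)
        test_scores.append(test_score)
        log.info("fold %d: best T_MIC=%.3f lr=%.3g train=%.3f test=%.3f", train_idx,
                 best["threshold"], best["learning_rate"], best["train_overall"], test_score)
    return CvResult(best_by_fold=best_by_fold,
                    mean_test_overall=float(np.mean(test_scores)),
                    score_table=table, folds=folds)
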