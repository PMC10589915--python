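"""Candidate-regulator pruning by MIC thresholding.

For each target gene j the candidates are every other gene (or, when a
transcription-factor list is supplied, every other TF).  A candidate i is
retained when ``MIC(i, j) > threshold`` (strict, per the network-inference
convention of "retain if the threshold is exceeded").  Raising the threshold
therefore never enlarges a set.  A target whose every candidate falls below
the threshold would be left with an empty design matrix, so the top
``min_regulators`` candidates by MIC are kept as a fallback — the pruning is
meant to shrink regulator sets, never to drop targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionDataset
from .mic import MicMatrix

__all__ = ["RegulatorSets", "select_regulators", "build_regulator_sets"]


@dataclass
class RegulatorSets:
    """Per-target ordered candidate-regulator lists."""

    by_target: dict[str, list[str]]
    threshold_used: float

    def __getitem__(self, target: str) -> list[str]:
        return self.by_target[target]

    def to_tsv(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            for target, regs in self.by_target.items():
                fh.write(f"{target}\t{','.join(regs)}\n")


def select_regulators(mic: MicMatrix, target: str, threshold: float,
                      tf_restriction=None, min_regulators: int = 3) -> list[str]:
    """Candidates i != target with MIC(i, target) above threshold.

    Ordered by MIC descending, ties by gene name ascending.  If fewer than
    ``min_regulators`` pass, the top ``min_regulators`` candidates by MIC
    are returned instead (all candidates when fewer exist).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    if min_regulators < 1:
        raise ValueError("min_regulators must be >= 1")
    j = mic.genes.index_of(target)
    names = mic.genes.names
    allowed = set(names if tf_restriction is None else tf_restriction)
    candidates = []
    for i, name in enumerate(names):
        if i == j or name not in allowed:
            continue
        score = mic.scores[i, j]
        if np.isnan(score):
            raise ValueError(f"MIC undefined for pair ({name}, {target})")
        candidates.append((name, float(score)))
    candidates.sort(key=lambda c: (-c[1], c[0]))
    kept = [name for name, s in candidates if s > threshold]
    if len(kept) < min_regulators:
        kept = [name for name, _ in candidates[:min_regulators]]
    return kept


def build_regulator_sets(mic: MicMatrix, dataset: ExpressionDataset,
                         threshold: float, min_regulators: int = 3) -> RegulatorSets:
    """One pruned regulator list per target gene; deterministic."""
    tf = dataset.tf_names
    by_target = {
        target: select_regulators(mic, target, threshold, tf_restriction=tf,
                                  min_regulators=min_regulators)
        for target in dataset.genes.names
    }
    return RegulatorSets(by_target, threshold)
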