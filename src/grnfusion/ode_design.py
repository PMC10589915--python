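"""Supervised regression problems from the non-linear ODE view of regulation.

The expression of a target gene j is modeled as

    dx_j/dt + c_j * x_j = f_j(x_{i1}, ..., x_{iM}),

where c_j is a first-order decay rate and f_j an arbitrary function of the
expression of j's candidate regulators.  Discretizing the derivative with a
forward difference over a lag of ``b`` index steps turns each time-series
window into a training pair:

    features = regulator expression at the earlier time t_k,
    response  = (x_{k+b,j} - x_{k,j}) / (t_{k+b} - t_k) + c * x_{k,j}.

At steady state the derivative vanishes, so each perturbation condition
contributes the pair (regulator expression, c * x_j).  Stacking the
time-series blocks (experiment order) and then the steady block yields the
design matrix used to fit f_j; its row count is exactly
``sum_e (T_e - b) + S``.

Features are taken at the earlier time to preserve causality; the target's
own expression is never a feature.  No scaling is applied — the downstream
tree ensembles are invariant to monotone feature transforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionDataset, SteadyStateMatrix, TimeSeriesExperiment

__all__ = ["OdeConfig", "DesignMatrix", "build_timeseries_rows",
           "build_steadystate_rows", "assemble_design"]


@dataclass(frozen=True)
class OdeConfig:
    """Decay rate and difference-equation lag.

    decay_rate
        Global first-order decay constant c (per-gene overrides via
        ``decay_overrides``); setting an exact per-gene value is rarely
        possible, so a single constant is the default treatment.
    lag
        Index lag b of the forward difference, in sampling steps.
    """

    decay_rate: float = 1.0
    lag: int = 1
    decay_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.decay_rate < 0:
            raise ValueError("decay rate must be >= 0")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")

    def decay_for(self, gene: str) -> float:
        return self.decay_overrides.get(gene, self.decay_rate)


@dataclass
class DesignMatrix:
    """Feature matrix (columns = regulators, in order) plus response vector."""

    features: np.ndarray
    responses: np.ndarray
    regulators: list[str]
    row_provenance: list[str]

    def __post_init__(self) -> None:
        if self.features.shape != (len(self.responses), len(self.regulators)):
            raise ValueError("inconsistent design-matrix shapes")
        if not (np.all(np.isfinite(self.features)) and np.all(np.isfinite(self.responses))):
            raise ValueError("non-finite cells in design matrix")

    @property
    def n_rows(self) -> int:
        return len(self.responses)

    def to_tsv(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("\t".join(["provenance", *self.regulators, "response"]) + "\n")
            for tag, row, y in zip(self.row_provenance, self.features, self.responses):
                cells = [tag, *(f"{v:.10g}" for v in row), f"{y:.10g}"]
                fh.write("\t".join(cells) + "\n")


def _columns(genes, names: list[str]) -> np.ndarray:
    return np.array([genes.index_of(n) for n in names], dtype=int)


def build_timeseries_rows(exp: TimeSeriesExperiment, genes, target: str,
                          regulators: list[str], cfg: OdeConfig,
                          experiment_id: int = 0) -> DesignMatrix:
    """Difference-equation rows from one experiment: T - b rows.

    Emits an empty design (with a warning) when the experiment is shorter
    than the lag allows.
    """
    b = cfg.lag
    c = cfg.decay_for(target)
    j = genes.index_of(target)
    cols = _columns(genes, regulators)
    T = exp.n_times
    if T <= b:
        warnings.warn(f"experiment {experiment_id} has T={T} <= lag={b}; no rows emitted",
                      stacklevel=2)
        return DesignMatrix(np.empty((0, len(regulators))), np.empty(0), list(regulators), [])
    x_j = exp.values[:, j]
    dt = exp.times[b:] - exp.times[:-b]
    responses = (x_j[b:] - x_j[:-b]) / dt + c * x_j[:-b]
    features = exp.values[:-b][:, cols]
    prov = [f"ts:{experiment_id}:t{k}" for k in range(T - b)]
    return DesignMatrix(features, responses, list(regulators), prov)


def build_steadystate_rows(ss: SteadyStateMatrix, genes, target: str,
                           regulators: list[str], cfg: OdeConfig) -> DesignMatrix:
    """Steady-state rows: one per condition, response c * x_j."""
    c = cfg.decay_for(target)
    j = genes.index_of(target)
    cols = _columns(genes, regulators)
    features = ss.values[:, cols]
    responses = c * ss.values[:, j]
    labels = ss.condition_labels or [str(e) for e in range(ss.n_conditions)]
    prov = [f"ss:{lab}" for lab in labels]
    return DesignMatrix(features, responses, list(regulators), prov)


def assemble_design(dataset: ExpressionDataset, target: str, regulators: list[str],
                    cfg: OdeConfig | None = None) -> DesignMatrix:
    """Stack time-series blocks (experiment order) then the steady block."""
    cfg = cfg or OdeConfig()
    if target in regulators:
        raise ValueError(f"target {target!r} may not be its own regulator")
    parts = [
        build_timeseries_rows(exp, dataset.genes, target, regulators, cfg, experiment_id=e)
        for e, exp in enumerate(dataset.ts_experiments)
    ]
    if dataset.steady is not None and dataset.steady.n_conditions > 0:
        parts.append(build_steadystate_rows(dataset.steady, dataset.genes, target,
                                            regulators, cfg))
    total = sum(p.n_rows for p in parts)
    if total == 0:
        raise ValueError(f"target {target!r} yields no training rows (unmodelable)")
    return DesignMatrix(
        np.vstack([p.features for p in parts]),
        np.concatenate([p.responses for p in parts]),
        list(regulators),
        [tag for p in parts for tag in p.row_provenance],
    )
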