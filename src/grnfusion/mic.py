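"""Maximal Information Coefficient (MIC) estimation between expression vectors.

The MIC of two vectors is the maximum, over all grids drawn on the scatter
plot of the pair, of the grid's mutual information normalized by
``log2(min(m, n))``, where ``m`` and ``n`` are the numbers of columns and
rows.  Admissible grids satisfy ``m, n >= 2`` and the resolution bound
``m * n < N ** alpha`` (``alpha`` defaults to 0.6, the conventional
exponent).  Cut points are only ever placed between consecutive distinct
sample values, so MIC depends on the data solely through rank order: it is
invariant under strictly increasing transformations of either variable and
tied values are never split across bins.

Two search strategies are used:

* **exhaustive** — for small samples (``N <= exhaustive_cutoff``) every
  admissible placement of cut points is enumerated; the result is the exact
  maximum;
* **approximate** — for larger samples, one axis is equipartitioned by mass
  and the other is optimized by dynamic programming over a capped set of
  candidate boundaries ("superclumps"), in both orientations.  This is the
  standard MINE-style approximation.

Degenerate inputs (constant vectors, samples too small to admit any grid)
score 0 rather than raising, so a flat gene simply attracts no regulators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .data_io import ExpressionDataset, GeneIndex

__all__ = ["MicConfig", "MicMatrix", "mutual_information", "mic", "mic_matrix"]


@dataclass(frozen=True)
class MicConfig:
    """Tunable knobs of the MIC estimator.

    alpha
        Exponent of the grid-resolution bound ``m * n < N ** alpha``.
    exhaustive_cutoff
        Largest sample size for which the exact exhaustive search runs.
    clump_factor
        In the approximate search, the optimized axis offers at most
        ``clump_factor * m_max`` candidate boundaries.
    zscore
        Whether to z-score each gene's pooled vector before pairing.  MIC is
        rank-based so this does not change scores; it is exposed for parity
        with pipelines that standardize for other estimators.
    """

    alpha: float = 0.6
    exhaustive_cutoff: int = 25
    clump_factor: int = 15
    zscore: bool = False


@dataclass
class MicMatrix:
    """Symmetric G x G matrix of pairwise MIC scores (NaN where undefined)."""

    scores: np.ndarray
    genes: GeneIndex

    def __getitem__(self, pair: tuple[int, int]) -> float:
        return float(self.scores[pair])

    def to_tsv(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("\t".join(self.genes.names) + "\n")
            for row in self.scores:
                fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "MicMatrix":
        with open(path, "rt", encoding="utf-8") as fh:
            genes = GeneIndex(tuple(fh.readline().rstrip("\n").split("\t")))
            scores = np.loadtxt(fh, delimiter="\t", ndmin=2)
        if scores.shape != (len(genes), len(genes)):
            raise ValueError("MIC matrix shape does not match its gene header")
        return cls(scores, genes)


def _plogp(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with the 0 log 0 := 0 convention."""
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def mutual_information(joint_counts) -> float:
    """Mutual information, in bits, of an m x n contingency table of counts.

    ``I = sum p(x, y) log2[p(x, y) / (p(x) p(y))]``; zero cells contribute
    nothing.  A table whose mass sits in a single row or column has I = 0.
    """
    counts = np.asarray(joint_counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("joint_counts must be a 2-D array")
    if np.any(counts < 0):
        raise ValueError("negative cell count")
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero contingency table")
    if (counts.sum(axis=1) > 0).sum() < 2 or (counts.sum(axis=0) > 0).sum() < 2:
        return 0.0  # a single non-empty row or column carries no information
    p = counts / total
    # I = H(row) + H(col) - H(joint), all in bits
    h_joint = -_plogp(p).sum()
    h_row = -_plogp(p.sum(axis=1)).sum()
    h_col = -_plogp(p.sum(axis=0)).sum()
    return max(0.0, h_row + h_col - h_joint)


# ---------------------------------------------------------------------------
# internal machinery: everything operates on "distinct-group codes", i.e. the
# index of each sample's value among the sorted distinct values of its axis.
# A grid boundary is a gap index g separating codes <= g from codes > g.


def _codes(v: np.ndarray) -> tuple[np.ndarray, int]:
    """Map samples to 0-based indices of their sorted distinct values."""
    _, codes = np.unique(v, return_inverse=True)
    return codes, int(codes.max()) + 1


def _grid_sizes(n_samples: int, alpha: float) -> list[tuple[int, int]]:
    """All (m, n) with m, n >= 2 and m * n < n_samples ** alpha."""
    bound = float(n_samples) ** alpha
    out = []
    m = 2
    while m * 2 < bound:
        n = 2
        while m * n < bound:
            out.append((m, n))
            n += 1
        m += 1
    return out


def _equipartition_gaps(codes: np.ndarray, n_groups: int, n_bins: int) -> np.ndarray | None:
    """Choose n_bins - 1 gap indices splitting the mass as evenly as ties allow.

    Returns None when fewer than n_bins distinct groups exist.
    """
    if n_groups < n_bins:
        return None
    group_sizes = np.bincount(codes, minlength=n_groups)
    cum = np.cumsum(group_sizes)  # cum[g] = #samples with code <= g
    total = cum[-1]
    targets = total * np.arange(1, n_bins) / n_bins
    gaps = np.empty(n_bins - 1, dtype=int)
    prev = -1
    for i, t in enumerate(targets):
        g = int(np.argmin(np.abs(cum[:-1] - t)))
        g = max(g, prev + 1)  # boundaries must stay strictly increasing
        g = min(g, n_groups - 2 - (n_bins - 2 - i))  # leave room for the rest
        gaps[i] = g
        prev = g
    return gaps


def _bin_by_gaps(codes: np.ndarray, gaps: np.ndarray) -> np.ndarray:
    return np.searchsorted(gaps, codes, side="left").astype(np.intp)


def _mic_exhaustive(xc: np.ndarray, nx: int, yc: np.ndarray, ny: int,
                    sizes: list[tuple[int, int]]) -> float:
    """Exact maximum over every admissible cut-point placement."""
    N = len(xc)
    x_gaps = np.arange(nx - 1)
    y_gaps = np.arange(ny - 1)
    best = 0.0
    # cache y binnings per (n, gap combination) is wasteful; sizes are tiny,
    # recompute per combination instead.
    for m, n in sizes:
        if nx < m or ny < n:
            continue
        norm = np.log2(min(m, n))
        for gx in combinations(x_gaps, m - 1):
            xb = _bin_by_gaps(xc, np.asarray(gx))
            for gy in combinations(y_gaps, n - 1):
                yb = _bin_by_gaps(yc, np.asarray(gy))
                counts = np.bincount(xb * n + yb, minlength=m * n).reshape(m, n)
                i = mutual_information(counts)
                score = i / norm
                if score > best:
                    best = score
    return min(best, 1.0)


def _superclump_gaps(codes: np.ndarray, n_groups: int, max_cells: int) -> np.ndarray:
    """Candidate boundaries for the optimized axis, capped at max_cells cells."""
    if n_groups - 1 <= max_cells - 1:
        return np.arange(n_groups - 1)
    gaps = _equipartition_gaps(codes, n_groups, max_cells)
    assert gaps is not None
    return gaps


def _optimize_axis(xc: np.ndarray, nx: int, y_bins: np.ndarray, n: int,
                   m_max: int, clump_factor: int) -> np.ndarray:
    """Best achievable MI for each column count 2..m_max against fixed rows.

    Dynamic program over candidate column boundaries; returns an array
    ``best[l]`` (index 0 -> l = 2) of mutual informations in bits.
    """
    N = len(xc)
    cand = _superclump_gaps(xc, nx, clump_factor * m_max)
    cells = _bin_by_gaps(xc, cand)  # P candidate cells
    P = len(cand) + 1
    counts = np.zeros((P, n))
    np.add.at(counts, (cells, y_bins), 1.0)
    cum = np.vstack([np.zeros(n), np.cumsum(counts, axis=0)])  # (P+1, n)
    # W[s, p]: contribution of a column spanning cells s..p-1:
    #   -(tot/N) log2(tot/N) + sum_q (c_q/N) log2(c_q/N)
    diff = (cum[None, :, :] - cum[:, None, :]) / N
    tot = diff.sum(axis=2)
    with np.errstate(invalid="ignore"):
        W = -_plogp(tot) + _plogp(diff).sum(axis=2)
    W[tot <= 0] = -np.inf  # empty columns are not allowed
    h_rows = -_plogp(np.bincount(y_bins, minlength=n) / N).sum()
    best = np.full(m_max - 1, 0.0)
    F = W[0].copy()  # F[p]: objective of 1 column over cells [0, p)
    for l in range(2, m_max + 1):
        cand_scores = F[:, None] + W  # choose last boundary s, column [s, p)
        F = cand_scores.max(axis=0)
        obj = F[P]
        if np.isfinite(obj):
            best[l - 2] = max(0.0, obj + h_rows)
    return best


def _mic_approx(xc: np.ndarray, nx: int, yc: np.ndarray, ny: int,
                sizes: list[tuple[int, int]], clump_factor: int) -> float:
    best = 0.0
    by_rows: dict[int, int] = {}
    for m, n in sizes:
        by_rows[n] = max(by_rows.get(n, 0), m)
    for axes in ((xc, nx, yc, ny), (yc, ny, xc, nx)):
        oc, on, fc, fn = axes
        for n, m_max in by_rows.items():
            gaps = _equipartition_gaps(fc, fn, n)
            if gaps is None:
                continue
            y_bins = _bin_by_gaps(fc, gaps)
            n_eff = int(y_bins.max()) + 1
            if n_eff < 2 or on < 2:
                continue
            mis = _optimize_axis(oc, on, y_bins, n_eff, m_max, clump_factor)
            for l in range(2, m_max + 1):
                score = mis[l - 2] / np.log2(min(l, n))
                if score > best:
                    best = score
    return min(best, 1.0)


def mic(x, y, alpha: float = 0.6, config: MicConfig | None = None) -> float:
    """Maximal Information Coefficient of two equal-length vectors, in [0, 1].

    Parameters
    ----------
    x, y
        Finite numeric vectors of equal length N.
    alpha
        Grid bound exponent; admissible grids satisfy ``m * n < N ** alpha``
        (strict).  Ignored when ``config`` is given.
    config
        Full estimator configuration; overrides ``alpha``.
    """
    cfg = config if config is not None else MicConfig(alpha=alpha)
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input vectors")
    N = len(x)
    sizes = _grid_sizes(N, cfg.alpha) if N > 0 else []
    if not sizes:
        warnings.warn(f"no admissible grid for N={N} at alpha={cfg.alpha}; MIC defined as 0",
                      stacklevel=2)
        return 0.0
    xc, nx = _codes(x)
    yc, ny = _codes(y)
    if nx < 2 or ny < 2:  # constant vector
        return 0.0
    if N <= cfg.exhaustive_cutoff:
        return _mic_exhaustive(xc, nx, yc, ny, sizes)
    return _mic_approx(xc, nx, yc, ny, sizes, cfg.clump_factor)


def mic_matrix(dataset: ExpressionDataset, candidate_regulators=None,
               config: MicConfig | None = None) -> MicMatrix:
    """Pairwise MIC over each gene's pooled expression vector.

    Each gene contributes one vector: all time points of all experiments in
    order, then all steady-state rows.  Entry (i, j) is computed once per
    unordered pair and mirrored; the diagonal is NaN.  When
    ``candidate_regulators`` (gene names) is given, pairs where neither gene
    is a candidate are skipped and left NaN.
    """
    cfg = config or MicConfig()
    pooled = dataset.pooled_matrix()
    if pooled.shape[0] < 4:
        raise ValueError("need at least 4 pooled samples per gene for MIC")
    if cfg.zscore:
        sd = pooled.std(axis=0)
        sd[sd == 0] = 1.0
        pooled = (pooled - pooled.mean(axis=0)) / sd
    G = len(dataset.genes)
    if candidate_regulators is None:
        cand = set(range(G))
    else:
        cand = {dataset.genes.index_of(n) for n in candidate_regulators}
    scores = np.full((G, G), np.nan)
    for i in range(G):
        for j in range(i + 1, G):
            if i not in cand and j not in cand:
                continue
            try:
                s = mic(pooled[:, i], pooled[:, j], config=cfg)
            except ValueError as err:
                raise ValueError(
                    f"MIC failed for pair ({dataset.genes.names[i]}, "
                    f"{dataset.genes.names[j]}): {err}") from err
            scores[i, j] = scores[j, i] = s
    return MicMatrix(scores, dataset.genes)
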