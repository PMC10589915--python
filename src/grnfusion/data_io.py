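"""Readers and writers for DREAM4-dialect expression tables and edge lists.

Formats handled
---------------
* time-series TSV: a header line with a time column followed by gene names,
  one or more blank-line-separated experiment blocks;
* steady-state TSV: a gene-name header, one row per perturbation condition;
* transcription-factor lists: one identifier per line;
* gold-standard edge lists: ``regulator<TAB>target<TAB>{0,1}``;
* ranked-edge output: ``regulator<TAB>target<TAB>score`` sorted by score.

Gene identifiers are case-sensitive and matched exactly.  Missing or
non-numeric values are hard errors — these dialects carry no NA convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FormatError",
    "ValidationError",
    "GeneIndex",
    "TimeSeriesExperiment",
    "SteadyStateMatrix",
    "ExpressionDataset",
    "GoldStandard",
    "RankedEdgeList",
    "read_timeseries",
    "read_steadystate",
    "read_tf_list",
    "read_gold_standard",
    "read_ranked_edges",
    "write_ranked_edges",
    "write_timeseries",
    "write_steadystate",
    "write_gold_standard",
]


class FormatError(ValueError):
    """A file does not conform to its dialect (ragged rows, bad labels...)."""


class ValidationError(ValueError):
    """Well-formed input that violates a semantic invariant."""


@dataclass(frozen=True)
class GeneIndex:
    """Ordered list of unique gene identifiers; the canonical column order."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) < 2:
            raise ValidationError("a gene index needs at least 2 genes")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("duplicate gene identifiers in header")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown gene identifier {name!r}") from None


@dataclass
class TimeSeriesExperiment:
    """One time-course: strictly increasing times and a T x G value matrix."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 2:
            raise ValidationError("times must be 1-D and values 2-D")
        if len(self.times) != self.values.shape[0]:
            raise ValidationError("one value row per time stamp required")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("time stamps must be strictly increasing")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite entries in time-series data")

    @property
    def n_times(self) -> int:
        return len(self.times)


@dataclass
class SteadyStateMatrix:
    """S x G matrix of equilibrium expression, one row per condition."""

    values: np.ndarray
    condition_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("steady-state values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite entries in steady-state data")
        if self.condition_labels is not None and len(self.condition_labels) != self.values.shape[0]:
            raise ValidationError("one condition label per row required")

    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]


@dataclass
class ExpressionDataset:
    """Time-series experiments and a steady-state matrix over one gene list.

    ``tf_names``, when given, restricts which genes may act as regulators
    (the transcription-factor list of TF-restricted tasks).
    """

    genes: GeneIndex
    ts_experiments: list[TimeSeriesExperiment] = field(default_factory=list)
    steady: SteadyStateMatrix | None = None
    tf_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        G = len(self.genes)
        for exp in self.ts_experiments:
            if exp.values.shape[1] != G:
                raise ValidationError("experiment column count differs from gene index")
        if self.steady is not None and self.steady.values.shape[1] != G:
            raise ValidationError("steady-state column count differs from gene index")
        has_ts = any(e.n_times > 0 for e in self.ts_experiments)
        has_ss = self.steady is not None and self.steady.n_conditions > 0
        if not has_ts and not has_ss:
            raise ValidationError("dataset holds neither time-series nor steady-state rows")
        if self.tf_names is not None:
            unknown = set(self.tf_names) - set(self.genes.names)
            if unknown:
                raise ValidationError(f"TF names not in gene index: {sorted(unknown)}")

    def pooled_matrix(self) -> np.ndarray:
        """All expression rows stacked: time-series blocks in order, then steady rows."""
        blocks = [e.values for e in self.ts_experiments if e.n_times > 0]
        if self.steady is not None and self.steady.n_conditions > 0:
            blocks.append(self.steady.values)
        return np.vstack(blocks)


@dataclass
class GoldStandard:
    """Known directed regulatory edges; optionally explicit negatives."""

    positive_edges: frozenset[tuple[str, str]]
    known_negative_edges: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        for r, t in self.positive_edges | self.known_negative_edges:
            if r == t:
                raise ValidationError(f"self-edge {r}->{t} in gold standard")
        if self.positive_edges & self.known_negative_edges:
            raise ValidationError("edge labeled both positive and negative")

    @property
    def n_positives(self) -> int:
        return len(self.positive_edges)


@dataclass
class RankedEdgeList:
    """Directed edges sorted by score descending.

    Ties are broken by (regulator, target) lexicographic ascending so output
    files are byte-reproducible.
    """

    edges: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        for r, t, s in self.edges:
            if r == t:
                raise ValidationError(f"self-edge {r}->{t} in ranked list")
            if not np.isfinite(s) or s < 0:
                raise ValidationError(f"score for {r}->{t} must be finite and >= 0")
        self.edges = sorted(self.edges, key=lambda e: (-e[2], e[0], e[1]))

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)


# ---------------------------------------------------------------------------
# readers


def _parse_float(token: str, where: str) -> float:
    try:
        v = float(token)
    except ValueError:
        raise FormatError(f"non-numeric cell {token!r} {where}") from None
    if not np.isfinite(v):
        raise FormatError(f"non-finite cell {token!r} {where}")
    return v


def _split_blocks(lines: list[str]) -> list[list[str]]:
    blocks: list[list[str]] = []
    current: list[str] = []
    for line in lines:
        if line.strip() == "":
            if current:
                blocks.append(current)
                current = []
        else:
            current.append(line.rstrip("\n"))
    if current:
        blocks.append(current)
    return blocks


def read_timeseries(path, dialect: str = "dream4") -> tuple[list[TimeSeriesExperiment], GeneIndex]:
    """Read a blank-line-delimited multi-experiment time-series table.

    The first header token is treated as the time column whatever its label;
    gene order is taken verbatim from the header.  ``tidy`` dialect is the
    same grid without blank-line block separation (a single experiment).
    """
    if dialect not in ("dream4", "tidy"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "rt", encoding="utf-8") as fh:
        lines = fh.readlines()
    blocks = _split_blocks(lines)
    if not blocks:
        raise FormatError(f"{path}: empty file")
    header = blocks[0][0].split("\t")
    if len(header) < 3:
        raise FormatError(f"{path}: header needs a time column and >= 2 genes")
    genes = GeneIndex(tuple(h.strip() for h in header[1:]))
    width = len(header)
    if dialect == "tidy":
        body = [row for block in blocks for row in block]
        blocks = [body]
    experiments = []
    for b, block in enumerate(blocks):
        rows = block[1:] if b == 0 else block
        # repeated headers on later blocks are tolerated (DREAM4 files vary)
        if b > 0 and rows and rows[0].split("\t")[0] == header[0]:
            rows = rows[1:]
        if not rows:
            continue
        times, values = [], []
        for r, row in enumerate(rows):
            cells = row.split("\t")
            if len(cells) != width:
                raise FormatError(f"{path}: block {b + 1} row {r + 1} has {len(cells)} cells, expected {width}")
            where = f"at block {b + 1} row {r + 1} of {path}"
            times.append(_parse_float(cells[0], where))
            values.append([_parse_float(c, where) for c in cells[1:]])
        try:
            experiments.append(TimeSeriesExperiment(np.array(times), np.array(values)))
        except ValidationError as err:
            raise ValidationError(f"{path}: block {b + 1}: {err}") from None
    if not experiments:
        raise FormatError(f"{path}: no data rows")
    return experiments, genes


def read_steadystate(path, dialect: str = "dream4",
                     genes: GeneIndex | None = None) -> tuple[SteadyStateMatrix, GeneIndex]:
    """Read a steady-state matrix with a gene-name header.

    When ``genes`` is supplied the header must match it exactly.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = tuple(h.strip() for h in lines[0].split("\t"))
    file_genes = GeneIndex(header)
    if genes is not None and tuple(genes.names) != header:
        raise ValidationError(f"{path}: header does not match the expected gene index")
    values = []
    for r, row in enumerate(lines[1:]):
        cells = row.split("\t")
        if len(cells) != len(header):
            raise FormatError(f"{path}: row {r + 1} has {len(cells)} cells, expected {len(header)}")
        values.append([_parse_float(c, f"at row {r + 1} of {path}") for c in cells])
    mat = np.array(values, dtype=float) if values else np.empty((0, len(header)))
    return SteadyStateMatrix(mat), file_genes


def read_tf_list(path) -> tuple[str, ...]:
    """Read a transcription-factor list, one identifier per line."""
    with open(path, "rt", encoding="utf-8") as fh:
        names = [ln.strip() for ln in fh if ln.strip()]
    seen: dict[str, None] = {}
    for n in names:
        seen.setdefault(n)
    return tuple(seen)


def read_gold_standard(path) -> GoldStandard:
    """Read a 3-column edge list; label 1 rows are positives, 0 rows negatives."""
    positives: set[tuple[str, str]] = set()
    negatives: set[tuple[str, str]] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != 3:
                raise FormatError(f"{path}: line {i + 1} has {len(cells)} columns, expected 3")
            reg, tgt, label = cells[0].strip(), cells[1].strip(), cells[2].strip()
            if reg == tgt:
                raise ValidationError(f"{path}: line {i + 1} is a self-edge {reg}->{tgt}")
            if label == "1":
                positives.add((reg, tgt))
            elif label == "0":
                negatives.add((reg, tgt))
            else:
                raise FormatError(f"{path}: line {i + 1} label {label!r} not in {{0,1}}")
    return GoldStandard(frozenset(positives), frozenset(negatives - positives))


def read_ranked_edges(path) -> RankedEdgeList:
    """Read a ranked-edge TSV back into a :class:`RankedEdgeList`."""
    edges = []
    with open(path, "rt", encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != 3:
                raise FormatError(f"{path}: line {i + 1} has {len(cells)} columns, expected 3")
            edges.append((cells[0], cells[1], _parse_float(cells[2], f"at line {i + 1} of {path}")))
    return RankedEdgeList(edges)


# ---------------------------------------------------------------------------
# writers


def write_ranked_edges(ranked: RankedEdgeList, path) -> None:
    """Write ``regulator<TAB>target<TAB>score`` with >= 6 significant digits."""
    with open(path, "wt", encoding="utf-8") as fh:
        for reg, tgt, score in ranked:
            fh.write(f"{reg}\t{tgt}\t{score:.10g}\n")


def write_timeseries(experiments: list[TimeSeriesExperiment], genes: GeneIndex, path,
                     time_label: str = "Time") -> None:
    buf = io.StringIO()
    buf.write("\t".join((time_label, *genes.names)) + "\n")
    for b, exp in enumerate(experiments):
        if b > 0:
            buf.write("\n")
        for t, row in zip(exp.times, exp.values):
            # repr is the shortest exact round-trip form of a float
            buf.write("\t".join((repr(float(t)), *(repr(float(v)) for v in row))) + "\n")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def write_steadystate(steady: SteadyStateMatrix, genes: GeneIndex, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(genes.names) + "\n")
        for row in steady.values:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def write_gold_standard(gold: GoldStandard, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for reg, tgt in sorted(gold.positive_edges):
            fh.write(f"{reg}\t{tgt}\t1\n")
        for reg, tgt in sorted(gold.known_negative_edges):
            fh.write(f"{reg}\t{tgt}\t0\n")
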