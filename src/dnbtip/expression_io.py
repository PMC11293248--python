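"""Domain containers and plain-text readers/writers for the pipeline.

Expression matrices are tab-separated, genes as rows, with sample labels
that encode the time point and replicate (default dialect ``M{t}_R{r}``,
e.g. ``M6_R2`` = month 6, replicate 2).  Networks are two-column edge
lists; pathway annotation is GMT.  Values are assumed to be already
normalised / log-scaled; the pipeline never rescales them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("dnbtip")

__all__ = [
    "FormatError",
    "ExpressionSeries",
    "GeneNetwork",
    "PathwayMap",
    "AnalysisConfig",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_edge_list",
    "read_gmt",
]


class FormatError(ValueError):
    """Raised when an input file violates the documented layout."""


_LABEL_RE = re.compile(r"M(\d+)_R(\d+)$")


@dataclass
class ExpressionSeries:
    """A genes x samples expression matrix with time/replicate structure.

    Parameters
    ----------
    gene_ids
        Ordered, unique gene identifiers (rows of ``values``).
    sample_labels
        Ordered sample identifiers (columns of ``values``).
    time_of_sample
        Maps each sample label to its 1-based time index.
    replicate_of_sample
        Maps each sample label to its 1-based replicate index.
    values
        Expression values, shape ``(len(gene_ids), len(sample_labels))``.
    """

    gene_ids: list[str]
    sample_labels: list[str]
    time_of_sample: dict[str, int]
    replicate_of_sample: dict[str, int]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_labels = list(self.sample_labels)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            dup = next(g for g in self.gene_ids if g in seen or seen.add(g))
            raise FormatError(f"duplicate gene id {dup!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_labels)):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_labels)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression values must be finite")
        missing = [s for s in self.sample_labels if s not in self.time_of_sample]
        if missing:
            raise FormatError(f"samples without a time index: {missing}")
        counts: dict[int, int] = {}
        for s in self.sample_labels:
            counts[self.time_of_sample[s]] = counts.get(self.time_of_sample[s], 0) + 1
        thin = [t for t, c in counts.items() if c < 2]
        if thin:
            raise FormatError(
                f"time points with <2 samples (SD/PCC need replicates): {sorted(thin)}"
            )
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    # ---- convenience accessors -------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_labels)

    @property
    def times(self) -> list[int]:
        return sorted({self.time_of_sample[s] for s in self.sample_labels})

    def gene_index(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in series") from None

    def columns_at(self, t: int) -> list[int]:
        """Column indices of the samples measured at time ``t``."""
        cols = [i for i, s in enumerate(self.sample_labels) if self.time_of_sample[s] == t]
        if not cols:
            raise KeyError(f"no samples at time {t}")
        return cols

    def matrix_at(self, t: int) -> np.ndarray:
        """Genes x replicates sub-matrix for time point ``t``."""
        return self.values[:, self.columns_at(t)]

    def reordered(self, gene_order: list[str]) -> "ExpressionSeries":
        """Return a copy with rows permuted to ``gene_order``."""
        idx = [self.gene_index(g) for g in gene_order]
        return ExpressionSeries(
            gene_ids=list(gene_order),
            sample_labels=list(self.sample_labels),
            time_of_sample=dict(self.time_of_sample),
            replicate_of_sample=dict(self.replicate_of_sample),
            values=self.values[idx, :],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_labels)


@dataclass
class GeneNetwork:
    """Undirected gene network; each edge stored once as a sorted pair."""

    nodes: set[str]
    edges: set[tuple[str, str]]

    def __post_init__(self) -> None:
        canon = set()
        for a, b in self.edges:
            if a == b:
                raise FormatError(f"self-loop on {a!r}")
            if a not in self.nodes or b not in self.nodes:
                raise FormatError(f"edge ({a!r}, {b!r}) has endpoint outside node set")
            canon.add((a, b) if a <= b else (b, a))
        self.edges = canon
        self._adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for a, b in self.edges:
            self._adj[a].add(b)
            self._adj[b].add(a)

    def neighbors(self, gene: str) -> set[str]:
        try:
            return set(self._adj[gene])
        except KeyError:
            raise KeyError(f"gene {gene!r} not in network") from None

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class PathwayMap:
    """Mapping pathway id -> member gene set, with optional descriptions."""

    pathways: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [p for p, genes in self.pathways.items() if not genes]
        if empty:
            raise FormatError(f"pathways with empty gene sets: {empty}")

    def count(self, gene: str) -> int:
        """Number of pathways that contain ``gene``."""
        return sum(1 for genes in self.pathways.values() if gene in genes)


@dataclass
class AnalysisConfig:
    """Settings shared across the analysis stages.

    ``min_group_size``, ``sd_fold``, ``linkage_cut`` and ``epsilon`` control
    the dominant-group search (see :mod:`dnbtip.dnb_core`); ``fdr_threshold``
    and ``cluster_count`` control the differential-expression screen.
    """

    fdr_threshold: float = 0.05
    cluster_count: int = 9
    fuzzifier: float = 2.0
    min_group_size: int = 5
    sd_fold: float = 1.5
    linkage_cut: float = 0.65
    epsilon: float = 1e-3
    n_permutations: int = 199
    seed: int = 0
    baseline_time: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if self.cluster_count < 1:
            raise ValueError("cluster_count must be >= 1")
        if self.min_group_size < 2:
            raise ValueError("min_group_size must be >= 2")
        if self.sd_fold <= 0 or self.linkage_cut <= 0 or self.epsilon <= 0:
            raise ValueError("sd_fold, linkage_cut and epsilon must be > 0")


# ---- readers / writers ----------------------------------------------------


def _parse_label(label: str, pattern: re.Pattern[str]) -> tuple[int, int]:
    m = pattern.search(label)
    if m is None:
        raise FormatError(f"sample label {label!r} does not match the expected convention")
    return int(m.group(1)), int(m.group(2))


def read_expression_matrix(
    path,
    label_pattern: str | re.Pattern[str] = _LABEL_RE,
    sample_sheet: pd.DataFrame | None = None,
) -> ExpressionSeries:
    """Read a tab-separated genes x samples matrix.

    Sample time/replicate structure is taken from the column labels using
    ``label_pattern`` (default ``M{t}_R{r}``), or from ``sample_sheet``, a
    data frame with columns ``sample``, ``time``, ``replicate``.
    """
    pattern = re.compile(label_pattern) if isinstance(label_pattern, str) else label_pattern
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    dups = df.index[df.index.duplicated()]
    if len(dups):
        raise FormatError(f"duplicate gene id {dups[0]!r} in {path}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for gene, row in df.iterrows():
            for col, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"non-numeric value {cell!r} at gene {gene!r}, sample {col!r}"
                    ) from None
        raise
    labels = [str(c) for c in df.columns]
    if sample_sheet is not None:
        sheet = sample_sheet.set_index("sample")
        try:
            time_of = {s: int(sheet.loc[s, "time"]) for s in labels}
            rep_of = {s: int(sheet.loc[s, "replicate"]) for s in labels}
        except KeyError as exc:
            raise FormatError(f"sample sheet missing entry for {exc.args[0]!r}") from None
    else:
        parsed = {s: _parse_label(s, pattern) for s in labels}
        time_of = {s: tr[0] for s, tr in parsed.items()}
        rep_of = {s: tr[1] for s, tr in parsed.items()}
    return ExpressionSeries(gene_ids, labels, time_of, rep_of, values)


def write_expression_matrix(series: ExpressionSeries, path) -> None:
    """Write a series as TSV, preserving full float precision (%.17g)."""
    if series.n_genes == 0:
        raise ValueError("refusing to write a series with no genes")
    series.to_frame().to_csv(path, sep="\t", float_format="%.17g", index_label="gene")


def read_edge_list(path) -> GeneNetwork:
    """Read a two-column tab-separated edge list into a :class:`GeneNetwork`.

    Self-loops are dropped with a warning; duplicate edges (in either
    orientation) are collapsed.
    """
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated gene ids")
            a, b = parts
            nodes.update((a, b))
            if a == b:
                logger.warning("%s:%d: dropping self-loop on %r", path, lineno, a)
                continue
            edges.add((a, b) if a <= b else (b, a))
    return GeneNetwork(nodes=nodes, edges=edges)


def read_gmt(path) -> PathwayMap:
    """Read a GMT file (name, description, then member genes per line)."""
    pathways: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, desc, *genes = parts
            if name in pathways:
                raise FormatError(f"{path}:{lineno}: duplicate pathway id {name!r}")
            pathways[name] = {g for g in genes if g}
            descriptions[name] = desc
    return PathwayMap(pathways=pathways, descriptions=descriptions)
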