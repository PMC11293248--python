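"""Differential-expression screening and temporal-pattern clustering.

The across-time screen is a per-gene one-way ANOVA over the time groups
with Benjamini-Hochberg FDR control.  Per-month DEG sets are obtained by
Welch t-tests of each later month against the baseline month, again with
BH within each comparison, and summarised by their pairwise intersections
(the numbers behind an UpSet display).  Temporal profiles of selected
genes are standardized and soft-clustered into pattern templates by fuzzy
c-means.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import ExpressionSeries

logger = logging.getLogger("dnbtip")

__all__ = [
    "DEGResult",
    "ClusterAssignment",
    "DEGSetComparison",
    "test_deg_across_time",
    "bh_adjust",
    "deg_sets_vs_baseline",
    "standardize_profiles",
    "fuzzy_cmeans",
]


@dataclass
class DEGResult:
    """Per-gene across-time test results (F statistic, p, BH q, DEG flag)."""

    table: pd.DataFrame  # index gene; columns: stat, p, q, is_deg
    fdr_threshold: float

    @property
    def deg_genes(self) -> set[str]:
        return set(self.table.index[self.table["is_deg"]])


@dataclass
class ClusterAssignment:
    """Fuzzy c-means output: soft memberships plus hard argmax labels."""

    genes: list[str]
    membership: np.ndarray  # genes x c, rows sum to 1
    hard_labels: np.ndarray  # 1-based cluster id per gene
    c: int
    fuzzifier: float
    n_iter: int
    objective: float
    objective_history: list[float] = field(default_factory=list)
    centroids: np.ndarray | None = None

    def cluster_of(self, gene: str) -> int | None:
        try:
            return int(self.hard_labels[self.genes.index(gene)])
        except ValueError:
            return None


@dataclass
class DEGSetComparison:
    """Per-month DEG sets against the baseline, with their intersections."""

    sets: dict[str, set[str]]  # label -> DEG genes
    times: dict[str, int]  # label -> time index of the comparison
    pairwise: dict[tuple[str, str], int]
    smallest_overlap: str | None

    def size(self, label: str) -> int:
        return len(self.sets[label])


def _group_matrices(series: ExpressionSeries) -> dict[int, np.ndarray]:
    groups = {t: series.matrix_at(t) for t in series.times}
    for t, mat in groups.items():
        if mat.shape[1] < 2:
            raise ValueError(f"time {t} has fewer than 2 replicates")
    return groups


def test_deg_across_time(
    series: ExpressionSeries, fdr_threshold: float = 0.05
) -> DEGResult:
    """One-way ANOVA of each gene across the time groups, with BH control.

    Genes with zero total variance are untestable and get p = 1 (flagged).
    """
    groups = _group_matrices(series)
    if len(groups) < 2:
        raise ValueError("need at least 2 time points")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p = stats.f_oneway(*groups.values(), axis=1)
    total_sd = np.std(series.values, axis=1)
    degenerate = (total_sd == 0) | ~np.isfinite(p)
    if degenerate.any():
        logger.warning("%d gene(s) untestable (constant); p set to 1", degenerate.sum())
        f_stat = np.where(degenerate, 0.0, f_stat)
        p = np.where(degenerate, 1.0, p)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {"stat": f_stat, "p": p, "q": q, "is_deg": q < fdr_threshold},
        index=pd.Index(series.gene_ids, name="gene"),
    )
    return DEGResult(table=table, fdr_threshold=fdr_threshold)


test_deg_across_time.__test__ = False  # name is API, not a pytest test


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def deg_sets_vs_baseline(
    series: ExpressionSeries,
    baseline: int = 1,
    fdr_threshold: float = 0.05,
) -> DEGSetComparison:
    """Welch-t DEG sets of every non-baseline month vs the baseline month.

    BH is applied within each comparison.  All pairwise intersection sizes
    are recorded and the comparison with the smallest total overlap with
    the other comparisons is identified (ties go to the later month).
    """
    groups = _group_matrices(series)
    if baseline not in groups:
        raise ValueError(f"baseline time {baseline} not present")
    base = groups[baseline]
    sets: dict[str, set[str]] = {}
    times: dict[str, int] = {}
    gene_arr = np.asarray(series.gene_ids, dtype=object)
    for t in series.times:
        if t == baseline:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = stats.ttest_ind(groups[t], base, axis=1, equal_var=False)
        p = np.where(np.isfinite(p), p, 1.0)
        q = bh_adjust(p)
        label = f"M{baseline} vs M{t}"
        sets[label] = set(gene_arr[q < fdr_threshold])
        times[label] = t
    labels = list(sets)
    pairwise: dict[tuple[str, str], int] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            pairwise[(a, b)] = len(sets[a] & sets[b])
    smallest: str | None = None
    if len(labels) >= 2:
        def total_overlap(lab: str) -> int:
            return sum(v for k, v in pairwise.items() if lab in k)

        # ties go to the later time index
        smallest = min(labels, key=lambda lab: (total_overlap(lab), -times[lab]))
    return DEGSetComparison(sets=sets, times=times, pairwise=pairwise, smallest_overlap=smallest)


def standardize_profiles(
    series: ExpressionSeries, genes: list[str] | None = None
) -> pd.DataFrame:
    """Per-gene time profiles (mean over replicates), z-scored across time.

    Rows come out with mean 0 and SD 1 (ddof=1) over the T time points;
    zero-variance profiles are dropped with a warning.
    """
    genes = list(series.gene_ids) if genes is None else list(genes)
    idx = [series.gene_index(g) for g in genes]
    times = series.times
    means = np.column_stack([series.matrix_at(t).mean(axis=1)[idx] for t in times])
    sd = means.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(genes, keep) if not k]
        logger.warning("dropping %d flat profile(s): %s...", len(dropped), dropped[:5])
    z = (means[keep] - means[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return pd.DataFrame(
        z, index=[g for g, k in zip(genes, keep) if k], columns=[f"T{t}" for t in times]
    )


def fuzzy_cmeans(
    profiles: pd.DataFrame | np.ndarray,
    c: int,
    m: float = 2.0,
    tol: float = 1e-9,
    max_iter: int = 300,
    seed: int = 0,
) -> ClusterAssignment:
    """Classic fuzzy c-means on Euclidean distance.

    Memberships update as u_ik proportional to (1/d_ik^2)^(1/(m-1)), centroids as
    u^m-weighted means, until the objective sum(u^m d^2) changes by less
    than ``tol``.  Initial centroids are profiles drawn by a seeded RNG
    *after* putting rows in a canonical (lexicographic) order, so the
    result does not depend on input row order.  A profile exactly on a
    centroid receives membership 1 there.
    """
    if isinstance(profiles, pd.DataFrame):
        genes = [str(g) for g in profiles.index]
        x = profiles.to_numpy(dtype=float)
    else:
        x = np.asarray(profiles, dtype=float)
        genes = [f"g{i}" for i in range(x.shape[0])]
    n = x.shape[0]
    if c < 1:
        raise ValueError("c must be >= 1")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if c > n:
        raise ValueError(f"cannot fit {c} clusters to {n} profiles")

    canon = np.lexsort(x.T[::-1])  # row order independent of input order
    rng = np.random.default_rng(seed)
    init_idx = canon[rng.choice(n, size=c, replace=False)]
    centroids = x[init_idx].copy()

    u = np.full((n, c), 1.0 / c)
    history: list[float] = []
    prev_obj = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 0
        u = np.zeros_like(d2)
        on_centroid = zero.any(axis=1)
        if on_centroid.any():
            rows = np.where(on_centroid)[0]
            u[rows, np.argmax(zero[rows], axis=1)] = 1.0
        rest = ~on_centroid
        if rest.any():
            inv = d2[rest] ** (-1.0 / (m - 1.0))
            u[rest] = inv / inv.sum(axis=1, keepdims=True)
        obj = float(((u**m) * d2).sum())
        history.append(obj)
        if abs(prev_obj - obj) < tol:
            break
        prev_obj = obj
        w = u**m
        denom = w.sum(axis=0)
        empty = denom <= 0
        centroids = (w.T @ x) / np.where(empty, 1.0, denom)[:, None]
        if empty.any():  # a cluster lost all weight; park it on a far profile
            centroids[empty] = x[canon[rng.choice(n, size=int(empty.sum()))]]
    hard = u.argmax(axis=1) + 1
    return ClusterAssignment(
        genes=genes,
        membership=u,
        hard_labels=hard,
        c=c,
        fuzzifier=m,
        n_iter=n_iter,
        objective=history[-1],
        objective_history=history,
        centroids=centroids,
    )
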