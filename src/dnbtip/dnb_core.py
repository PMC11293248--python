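"""Criticality-index computation and tipping-point detection.

A dynamic network biomarker (DNB) is a dominant group of genes that, as a
system approaches a critical transition, shows (1) sharply increased
per-gene standard deviations, (2) sharply increased mutual Pearson
correlation, and (3) decreased correlation to the rest of the transcriptome.
The three signatures are combined into a single criticality index

    CI = SD_i * PCC_i / (PCC_o + eps)

where SD_i is the mean per-gene SD inside the group, PCC_i the mean
absolute pairwise correlation inside the group, PCC_o the mean absolute
correlation between group members and all other genes, and eps a small
guard against a vanishing denominator.  The time point at which the best
group's CI peaks is reported as the tipping point.

The dominant group at each time point is found by the classic recipe:
filter candidate genes by SD fold-change relative to a reference SD,
cluster candidates by average-linkage on correlation distance 1 - |r|,
and keep the highest-scoring cluster (sqrt(N)-weighted CI by default;
see DominantGroupConfig for the regime-specific defaults).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .expression_io import ExpressionSeries

logger = logging.getLogger("dnbtip")

__all__ = [
    "DominantGroupConfig",
    "CIComponents",
    "DNBResult",
    "per_time_sd",
    "pearson_matrix",
    "pooled_pearson_matrix",
    "reference_sd",
    "candidate_genes",
    "cluster_candidates",
    "compute_ci",
    "scan_time_points",
    "detect_tipping",
    "permutation_test",
]


@dataclass
class DominantGroupConfig:
    """Knobs of the dominant-group search.

    min_group_size
        Smallest cluster considered a candidate DNB (>= 2).
    sd_fold
        SD fold-change over the reference SD required of candidate genes.
        The screen is deliberately liberal (default 1.5): with only a
        handful of replicates a per-time SD estimate has very few degrees
        of freedom, and demanding the full design effect size in-sample
        costs a large fraction of true members.  Specificity is delegated
        to the clustering and CI stages.
    linkage_cut
        Cut height on the average-linkage dendrogram over distance 1 - |r|.
        The default 0.65 is matched to pooled-correlation clustering (see
        ``cluster_corr``), sitting between the expected distance inside a
        strongly co-fluctuating module (~0.45) and the null expectation
        (~0.84 at 24 df).  For per-time clustering a value around 0.4-0.5
        is more appropriate.
    epsilon
        Additive guard on the PCC_o denominator of the CI.
    baseline_time
        Time index treated as the reference state (excluded from the scan;
        also the reference SD when ``sd_reference="baseline"``).
    sd_reference
        ``"median"`` (default): a gene's reference SD is its median SD over
        all *other* time points, which is far more stable than a single
        time point's SD when replicates are few.  ``"baseline"``: the SD at
        ``baseline_time``, the literal reference-state reading.
    cluster_corr
        ``"pooled"`` (default): candidates are clustered on correlations
        computed over all samples after centering within each time point.
        Module membership is time-invariant, so pooling is valid for
        discovery and gives many more degrees of freedom than a single
        time point; the CI itself always uses per-time correlations.
        ``"per_time"``: cluster on the scanned time point's correlations.
    selection_weight
        Score used to pick the dominant group among a time point's
        clusters: ``"sqrt_n"`` (default) selects by sqrt(N) * CI, favouring
        larger coherent groups — small spurious clusters can reach high CI
        by selection alone when replicates are few — while ``"none"``
        selects by raw CI.  Reported CI values are never reweighted.
    """

    min_group_size: int = 5
    sd_fold: float = 1.5
    linkage_cut: float = 0.65
    epsilon: float = 1e-3
    baseline_time: int = 1
    sd_reference: str = "median"
    cluster_corr: str = "pooled"
    selection_weight: str = "sqrt_n"

    def __post_init__(self) -> None:
        if self.min_group_size < 2:
            raise ValueError("min_group_size must be >= 2")
        if self.sd_fold <= 0 or self.linkage_cut <= 0 or self.epsilon <= 0:
            raise ValueError("sd_fold, linkage_cut and epsilon must be > 0")
        if self.sd_reference not in ("median", "baseline"):
            raise ValueError("sd_reference must be 'median' or 'baseline'")
        if self.cluster_corr not in ("pooled", "per_time"):
            raise ValueError("cluster_corr must be 'pooled' or 'per_time'")
        if self.selection_weight not in ("sqrt_n", "none"):
            raise ValueError("selection_weight must be 'sqrt_n' or 'none'")


@dataclass
class CIComponents:
    """CI and its ingredients for one gene group at one time point."""

    time: int
    members: list[str]
    n: int
    sd_in: float
    pcc_in: float
    pcc_out: float
    ci: float


@dataclass
class DNBResult:
    """Outcome of a whole-series scan."""

    components: dict[int, CIComponents | None]
    ci_series: dict[int, float]
    tipping: int | None
    p_value: float | None = None
    config: DominantGroupConfig | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def tipping_group(self) -> list[str]:
        if self.tipping is None or self.components.get(self.tipping) is None:
            return []
        return list(self.components[self.tipping].members)


def per_time_sd(series: ExpressionSeries, t: int) -> np.ndarray:
    """Per-gene sample SD (ddof=1) over the replicates of time ``t``."""
    mat = series.matrix_at(t)
    if mat.shape[1] < 2:
        raise ValueError(f"time {t} has fewer than 2 replicates")
    return np.std(mat, axis=1, ddof=1)


def pearson_matrix(
    series: ExpressionSeries, t: int, genes: list[str] | None = None
) -> np.ndarray:
    """Pairwise Pearson correlation over the replicates of time ``t``.

    Rows/columns follow ``genes`` (default: all genes in series order).
    Pairs involving a zero-variance gene are recorded as 0 (flagged in the
    log); the diagonal is 1.
    """
    mat = series.matrix_at(t)
    if genes is not None:
        idx = [series.gene_index(g) for g in genes]
        mat = mat[idx, :]
    if mat.shape[1] < 2:
        raise ValueError(f"time {t} has fewer than 2 replicates")
    sd = np.std(mat, axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    corr = np.atleast_2d(corr)
    if degenerate.any():
        logger.warning(
            "t=%d: %d zero-variance gene(s); their correlations set to 0",
            t,
            int(degenerate.sum()),
        )
        corr[degenerate, :] = 0.0
        corr[:, degenerate] = 0.0
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def pooled_pearson_matrix(
    series: ExpressionSeries, genes: list[str] | None = None
) -> np.ndarray:
    """Correlation over all samples after centering within each time point.

    Removing per-time means strips both slow trends and planted mean
    shifts, leaving only replicate-level co-fluctuation, and pools the
    degrees of freedom of every time point.  Degenerate genes are handled
    as in :func:`pearson_matrix`.
    """
    mat = series.values.copy()
    if genes is not None:
        idx = [series.gene_index(g) for g in genes]
        mat = mat[idx, :]
    for t in series.times:
        cols = series.columns_at(t)
        mat[:, cols] -= mat[:, cols].mean(axis=1, keepdims=True)
    sd = np.std(mat, axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    corr = np.atleast_2d(corr)
    if degenerate.any():
        logger.warning(
            "pooled correlation: %d zero-variance gene(s) set to 0",
            int(degenerate.sum()),
        )
        corr[degenerate, :] = 0.0
        corr[:, degenerate] = 0.0
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def reference_sd(
    series: ExpressionSeries,
    t: int,
    baseline: int = 1,
    mode: str = "median",
    sd_by_time: dict[int, np.ndarray] | None = None,
) -> np.ndarray:
    """Per-gene reference SD against which time ``t`` is screened.

    ``mode="median"``: median over every time point except ``t`` (robust
    to a single perturbed time).  ``mode="baseline"``: the SD at the
    baseline time only.
    """
    if sd_by_time is None:
        sd_by_time = {s: per_time_sd(series, s) for s in series.times}
    if mode == "baseline":
        return sd_by_time[baseline]
    if mode == "median":
        others = [sd_by_time[s] for s in series.times if s != t]
        if not others:
            raise ValueError("median reference needs more than one time point")
        return np.median(np.column_stack(others), axis=1)
    raise ValueError(f"unknown sd_reference mode {mode!r}")


def candidate_genes(
    series: ExpressionSeries,
    t: int,
    baseline: int,
    sd_fold: float,
    sd_t: np.ndarray | None = None,
    sd_base: np.ndarray | None = None,
    sd_reference_mode: str = "median",
) -> list[str]:
    """Genes whose SD at ``t`` is at least ``sd_fold`` times the reference SD.

    The reference SD is :func:`reference_sd` (median over other time
    points by default, or the baseline time's SD).  Genes with zero
    reference SD are compared against the global median reference SD
    instead (flagged).
    """
    if t == baseline:
        raise ValueError("candidate screen needs t != baseline")
    sd_t = per_time_sd(series, t) if sd_t is None else sd_t
    if sd_base is None:
        sd_base = reference_sd(series, t, baseline=baseline, mode=sd_reference_mode)
    denom = sd_base.copy()
    zero = denom == 0
    if zero.any():
        fallback = float(np.median(sd_base))
        logger.warning(
            "t=%d: %d gene(s) with zero baseline SD; using median baseline SD %.3g",
            t,
            int(zero.sum()),
            fallback,
        )
        denom[zero] = fallback
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denom > 0, sd_t / np.where(denom > 0, denom, 1.0), np.inf)
        ratio = np.where((denom == 0) & (sd_t == 0), 0.0, ratio)
    keep = ratio >= sd_fold
    return [g for g, k in zip(series.gene_ids, keep) if k]


def cluster_candidates(
    pcc_matrix: np.ndarray,
    candidates: list[str],
    config: DominantGroupConfig,
) -> list[list[str]]:
    """Group candidate genes by average-linkage on distance 1 - |r|.

    ``pcc_matrix`` must be the correlation matrix over ``candidates`` in
    the given order.  The dendrogram is cut at ``config.linkage_cut``;
    groups smaller than ``config.min_group_size`` are discarded.  Genes
    are put in lexicographic order first so linkage ties resolve
    deterministically.
    """
    if len(candidates) < config.min_group_size:
        return []
    order = np.argsort(np.asarray(candidates, dtype=object))
    genes_sorted = [candidates[i] for i in order]
    dist = 1.0 - np.abs(pcc_matrix[np.ix_(order, order)])
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    tree = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(tree, t=config.linkage_cut, criterion="distance")
    groups: dict[int, list[str]] = {}
    for g, lab in zip(genes_sorted, labels):
        groups.setdefault(int(lab), []).append(g)
    kept = [sorted(v) for v in groups.values() if len(v) >= config.min_group_size]
    kept.sort(key=lambda grp: grp[0])
    return kept


def compute_ci(
    sd_vector: np.ndarray,
    pcc_matrix_all: np.ndarray,
    group_idx: list[int] | np.ndarray,
    epsilon: float = 1e-3,
    time: int = 0,
    gene_ids: list[str] | None = None,
) -> CIComponents:
    """Criticality index of one group against the rest of the genes.

    ``sd_vector`` and ``pcc_matrix_all`` cover all genes; ``group_idx``
    indexes the group members within them.
    """
    group_idx = np.asarray(group_idx, dtype=int)
    n_genes = len(sd_vector)
    n = len(group_idx)
    if n < 2:
        raise ValueError("group must contain at least 2 genes")
    if n >= n_genes:
        raise ValueError("PCC_o undefined: no genes outside the group")
    mask = np.zeros(n_genes, dtype=bool)
    mask[group_idx] = True

    sd_in = float(np.mean(sd_vector[group_idx]))
    sub = np.abs(pcc_matrix_all[np.ix_(group_idx, group_idx)])
    pcc_in = float((sub.sum() - np.trace(sub)) / (n * (n - 1)))
    cross = np.abs(pcc_matrix_all[group_idx][:, ~mask])
    pcc_out = float(cross.mean())
    if pcc_out < epsilon:
        logger.warning("t=%d: PCC_o %.3g below epsilon guard %.3g", time, pcc_out, epsilon)
    ci = sd_in * pcc_in / (pcc_out + epsilon)
    members = (
        [gene_ids[i] for i in group_idx] if gene_ids is not None else [str(i) for i in group_idx]
    )
    return CIComponents(
        time=time,
        members=sorted(members),
        n=n,
        sd_in=sd_in,
        pcc_in=pcc_in,
        pcc_out=pcc_out,
        ci=float(ci),
    )


def scan_time_points(
    series: ExpressionSeries, config: DominantGroupConfig | None = None
) -> DNBResult:
    """Score every non-baseline time point and locate the CI peak.

    For each time point: candidate genes by SD fold-change, candidate
    clustering, CI per cluster, best cluster kept.  The baseline time is
    assigned CI 0 with no group.  Ties at the peak go to the earliest time
    (flagged); if no time point yields a group the result carries the
    flag ``"no transition detected"``.
    """
    config = config or DominantGroupConfig()
    times = series.times
    if len(times) < 3:
        raise ValueError("need at least 3 time points to scan")
    if config.baseline_time not in times:
        raise ValueError(f"baseline time {config.baseline_time} not present")

    flags: list[str] = []
    sd_by_time = {t: per_time_sd(series, t) for t in times}
    pooled = pooled_pearson_matrix(series) if config.cluster_corr == "pooled" else None
    components: dict[int, CIComponents | None] = {}
    ci_series: dict[int, float] = {}
    gene_idx = {g: i for i, g in enumerate(series.gene_ids)}
    for t in times:
        if t == config.baseline_time:
            components[t] = None
            ci_series[t] = 0.0
            continue
        sd_t = sd_by_time[t]
        sd_ref = reference_sd(
            series, t, baseline=config.baseline_time,
            mode=config.sd_reference, sd_by_time=sd_by_time,
        )
        cands = candidate_genes(
            series, t, config.baseline_time, config.sd_fold, sd_t=sd_t, sd_base=sd_ref
        )
        if len(cands) < config.min_group_size or len(cands) >= series.n_genes:
            components[t] = None
            ci_series[t] = 0.0
            continue
        cand_idx = [gene_idx[g] for g in cands]
        if pooled is not None:
            cluster_corr = pooled
        else:
            cluster_corr = pearson_matrix(series, t)
        groups = cluster_candidates(cluster_corr[np.ix_(cand_idx, cand_idx)], cands, config)
        if not groups:
            components[t] = None
            ci_series[t] = 0.0
            continue
        corr_all = pearson_matrix(series, t) if pooled is not None else cluster_corr
        best: CIComponents | None = None
        best_score = -np.inf
        for grp in groups:
            if len(grp) >= series.n_genes:
                continue
            comp = compute_ci(
                sd_t,
                corr_all,
                [gene_idx[g] for g in grp],
                epsilon=config.epsilon,
                time=t,
                gene_ids=series.gene_ids,
            )
            score = comp.ci * (
                np.sqrt(comp.n) if config.selection_weight == "sqrt_n" else 1.0
            )
            if score > best_score:
                best, best_score = comp, score
        components[t] = best
        ci_series[t] = best.ci if best is not None else 0.0

    values = np.array([ci_series[t] for t in times])
    tipping = detect_tipping(values, times=times)
    if tipping is None:
        flags.append("no transition detected")
    elif (values == values.max()).sum() > 1:
        flags.append("tipping tie broken toward earliest time")
        logger.warning("CI peak tied; earliest time %s reported", tipping)
    return DNBResult(
        components=components,
        ci_series=ci_series,
        tipping=tipping,
        config=config,
        flags=flags,
    )


def detect_tipping(ci_series, times: list[int] | None = None) -> int | None:
    """Time label of the CI maximum; ``None`` if all values are 0.

    ``ci_series`` is ordered by time; ``times`` supplies the labels
    (default 1..len).  Ties resolve to the earliest time.
    """
    values = np.asarray(list(ci_series), dtype=float)
    if values.size == 0 or np.all(values == 0):
        return None
    labels = list(times) if times is not None else list(range(1, values.size + 1))
    return labels[int(np.argmax(values))]


def permutation_test(
    series: ExpressionSeries,
    config: DominantGroupConfig | None = None,
    n_perm: int = 199,
    seed: int = 0,
    return_null: bool = False,
):
    """Permutation p-value for the observed CI peak.

    The null is built by shuffling the sample-to-time assignment (columns
    relabelled wholesale) and re-running the scan; the p-value is
    ``(1 + #{null peak >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    config = config or DominantGroupConfig()
    observed = scan_time_points(series, config)
    obs_peak = max(observed.ci_series.values())
    rng = np.random.default_rng(seed)
    null_peaks = np.empty(n_perm)
    labels = series.sample_labels
    times = [series.time_of_sample[s] for s in labels]
    for i in range(n_perm):
        perm = rng.permutation(len(labels))
        time_of = {s: times[j] for s, j in zip(labels, perm)}
        shuffled = ExpressionSeries(
            gene_ids=series.gene_ids,
            sample_labels=labels,
            time_of_sample=time_of,
            replicate_of_sample=dict(series.replicate_of_sample),
            values=series.values,
        )
        null_peaks[i] = max(scan_time_points(shuffled, config).ci_series.values())
    p = float((1 + np.sum(null_peaks >= obs_peak)) / (n_perm + 1))
    if return_null:
        return p, obs_peak, null_peaks
    return p
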