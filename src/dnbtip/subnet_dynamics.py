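"""Correlation subnet of a focal gene around the tipping point.

For a focal gene (the paper-style "core DNB" candidate), computes its
absolute Pearson correlation to every other gene within each time point,
aggregates per-month rankings into an overall top-k list, and expresses
the correlation weights of a gene set around the tipping months as
normalized proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dnb_core import pearson_matrix
from .expression_io import ExpressionSeries

logger = logging.getLogger("dnbtip")

__all__ = [
    "CorrelationRanking",
    "WeightProportion",
    "focal_correlations",
    "aggregate_ranking",
    "weight_proportions",
]


@dataclass
class CorrelationRanking:
    focal: str
    per_time: dict[int, pd.Series]  # t -> |r| over other genes
    per_time_ranks: dict[int, pd.Series]  # t -> competition rank (1 = best)
    overall: list[tuple[str, float]]  # (gene, mean rank), ascending, length <= k


@dataclass
class WeightProportion:
    focal: str
    months: list[int]
    shares: pd.Series  # per gene in the evaluated set
    denominator: str = "set"  # shares sum to 1 when normalized within the set

    def __post_init__(self) -> None:
        total = float(self.shares.sum())
        if self.denominator == "set" and abs(total - 1.0) > 1e-9:
            raise ValueError(f"shares must sum to 1, got {total}")


def focal_correlations(
    series: ExpressionSeries, focal: str, t: int, variant: str = "abs"
) -> pd.Series:
    """Correlation weight between the focal gene and every other gene at ``t``.

    ``variant`` selects the weight definition: ``"abs"`` (default) |r|,
    ``"signed"`` raw r, ``"squared"`` r².  Degenerate (zero-variance)
    pairs are recorded as 0, matching
    :func:`dnbtip.dnb_core.pearson_matrix`.
    """
    i = series.gene_index(focal)  # raises KeyError if absent
    corr = pearson_matrix(series, t)
    row = corr[i]
    if variant == "abs":
        out = np.abs(row)
    elif variant == "signed":
        out = row
    elif variant == "squared":
        out = row**2
    else:
        raise ValueError(f"unknown correlation-weight variant {variant!r}")
    others = [g for g in series.gene_ids if g != focal]
    keep = [j for j in range(series.n_genes) if j != i]
    return pd.Series(out[keep], index=others, name=f"r@T{t}")


def _competition_ranks(abs_r: pd.Series) -> pd.Series:
    """Rank genes by descending |r|; ties share the smaller rank."""
    ranks = stats.rankdata(-abs_r.to_numpy(), method="min")
    return pd.Series(ranks.astype(int), index=abs_r.index)


def aggregate_ranking(
    rankings: dict[int, pd.Series], k: int = 20
) -> list[tuple[str, float]]:
    """Overall top-k genes by mean per-month competition rank.

    ``rankings`` maps time index to the per-gene |r| series for that
    month.  Ties in the mean rank break by ascending gene id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not rankings:
        raise ValueError("need at least one month of correlations")
    ranks = pd.DataFrame({t: _competition_ranks(s) for t, s in rankings.items()})
    mean_rank = ranks.mean(axis=1)
    ordered = sorted(mean_rank.items(), key=lambda kv: (kv[1], kv[0]))
    return [(g, float(s)) for g, s in ordered[:k]]


def build_ranking(
    series: ExpressionSeries, focal: str, times: list[int] | None = None, k: int = 20
) -> CorrelationRanking:
    """Per-month focal correlations plus the aggregated overall top-k."""
    times = series.times if times is None else list(times)
    per_time = {t: focal_correlations(series, focal, t) for t in times}
    per_ranks = {t: _competition_ranks(s) for t, s in per_time.items()}
    overall = aggregate_ranking(per_time, k=k)
    return CorrelationRanking(
        focal=focal, per_time=per_time, per_time_ranks=per_ranks, overall=overall
    )


def weight_proportions(
    series: ExpressionSeries,
    focal: str,
    gene_set: list[str],
    months: list[int],
    denominator: str = "set",
) -> WeightProportion:
    """Share of each gene in the total correlation weight around the tipping.

    share_i = mean_t |r(focal, i)| / sum_j mean_t |r(focal, j)| over the
    given ``months`` (typically the tipping month and the one before).
    With ``denominator="set"`` (default) the sum runs over the evaluated
    ``gene_set`` so displayed shares sum to 1; ``denominator="all"``
    normalizes against every gene in the series instead.  A zero
    denominator yields uniform shares (flagged).
    """
    if not months:
        raise ValueError("months must be non-empty")
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    if denominator not in ("set", "all"):
        raise ValueError("denominator must be 'set' or 'all'")
    per_month = pd.DataFrame(
        {t: focal_correlations(series, focal, t) for t in months}
    )
    all_means = per_month.mean(axis=1)
    means = all_means.loc[list(gene_set)]
    total = float(means.sum() if denominator == "set" else all_means.sum())
    if total == 0:
        logger.warning("all correlation weights zero; reporting uniform shares")
        shares = pd.Series(1.0 / len(gene_set), index=list(gene_set))
    else:
        shares = means / total
    return WeightProportion(
        focal=focal, months=list(months), shares=shares, denominator=denominator
    )
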