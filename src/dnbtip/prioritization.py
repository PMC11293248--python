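"""Ranking of DNB genes by four prioritization criteria.

Criterion 1: fraction of a gene's network neighbors that are DEGs.
Criterion 2: number of annotated pathways containing the gene.
Criterion 3: whether the gene is itself a DEG (1/0).
Criterion 4: whether the gene belongs to one of the temporal expression
clusters (1/0), with the cluster id reported for information.

The default combination treats the criteria as strict priorities
(lexicographic descending order); a rank-sum alternative averages the
per-criterion ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .deg_analysis import ClusterAssignment, DEGResult
from .expression_io import GeneNetwork, PathwayMap

logger = logging.getLogger("dnbtip")

__all__ = [
    "PriorityRecord",
    "deg_neighbor_ratio",
    "pathway_count",
    "build_priority_table",
    "rank_dnb_genes",
]


@dataclass
class PriorityRecord:
    gene: str
    deg_neighbor_ratio: float  # criterion 1
    pathway_count: int  # criterion 2
    is_deg: int  # criterion 3
    in_cluster: int  # criterion 4
    cluster_id: int | None = None
    rank: int | None = None


def deg_neighbor_ratio(network: GeneNetwork, deg_set: set[str], gene: str) -> float:
    """|neighbors intersect DEGs| / |neighbors|; isolated genes score 0."""
    if gene not in network.nodes:
        raise KeyError(f"gene {gene!r} not in network")
    nbrs = network.neighbors(gene)
    if not nbrs:
        return 0.0
    return len(nbrs & deg_set) / len(nbrs)


def pathway_count(pathways: PathwayMap, gene: str) -> int:
    """Number of annotated pathways that contain ``gene``."""
    return pathways.count(gene)


def build_priority_table(
    dnb_genes: list[str],
    network: GeneNetwork,
    deg_result: DEGResult,
    clusters: ClusterAssignment | None,
    pathways: PathwayMap,
) -> list[PriorityRecord]:
    """One unranked record per DNB gene with all four criteria filled.

    Genes absent from the network or annotation score 0 on the affected
    criterion (logged) so the ranking stays total.
    """
    if not dnb_genes:
        raise ValueError("empty DNB gene list")
    deg_set = deg_result.deg_genes
    records = []
    for gene in dnb_genes:
        if gene in network.nodes:
            ratio = deg_neighbor_ratio(network, deg_set, gene)
        else:
            logger.warning("gene %r absent from network; criterion 1 set to 0", gene)
            ratio = 0.0
        cluster_id = clusters.cluster_of(gene) if clusters is not None else None
        records.append(
            PriorityRecord(
                gene=gene,
                deg_neighbor_ratio=ratio,
                pathway_count=pathway_count(pathways, gene),
                is_deg=int(gene in deg_set),
                in_cluster=int(cluster_id is not None),
                cluster_id=cluster_id,
            )
        )
    return records


def rank_dnb_genes(records: list[PriorityRecord], mode: str = "lexicographic") -> list[PriorityRecord]:
    """Order records and assign ranks 1..n.

    ``lexicographic``: descending by (criterion1, criterion2, criterion3,
    criterion4), ties broken by ascending gene id.  ``ranksum``: average
    the per-criterion descending ranks (competition ranking) and order by
    ascending average, same tie-break.
    """
    if not records:
        raise ValueError("no records to rank")
    if mode == "lexicographic":
        ordered = sorted(
            records,
            key=lambda r: (
                -r.deg_neighbor_ratio,
                -r.pathway_count,
                -r.is_deg,
                -r.in_cluster,
                r.gene,
            ),
        )
    elif mode == "ranksum":
        crit = np.array(
            [
                [r.deg_neighbor_ratio, r.pathway_count, r.is_deg, r.in_cluster]
                for r in records
            ],
            dtype=float,
        )
        # competition rank, descending: rank = 1 + #{strictly better}
        scores = np.zeros(len(records))
        for j in range(crit.shape[1]):
            col = crit[:, j]
            scores += 1 + (col[None, :] > col[:, None]).sum(axis=1)
        scores /= crit.shape[1]
        ordered = [
            r
            for _, r in sorted(
                zip(scores, records), key=lambda sr: (sr[0], sr[1].gene)
            )
        ]
    else:
        raise ValueError(f"unknown ranking mode {mode!r}")
    out = []
    for i, r in enumerate(ordered, start=1):
        out.append(
            PriorityRecord(
                gene=r.gene,
                deg_neighbor_ratio=r.deg_neighbor_ratio,
                pathway_count=r.pathway_count,
                is_deg=r.is_deg,
                in_cluster=r.in_cluster,
                cluster_id=r.cluster_id,
                rank=i,
            )
        )
    return out
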