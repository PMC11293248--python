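"""End-to-end orchestration: simulate -> DEG/cluster -> DNB scan ->
prioritize -> subnet, from one YAML config, with seed control and a
machine-readable JSON report.

Config schema (``schema: 1``)::

    schema: 1
    seed: 17
    out_dir: results/run1
    simulate: true            # or false with explicit input paths
    simulation: {...}         # SimulationConfig overrides
    inputs:                   # used when simulate: false
      expression: expr.tsv
      network: network.tsv    # optional
      pathways: pathways.gmt  # optional
    analysis: {...}           # AnalysisConfig overrides
    permutations: 199         # 0 disables the permutation test
    focal_gene: null          # default: top-ranked DNB gene
    ranking_mode: lexicographic

The global seed fans out to per-stage seeds through fixed stage-name
hashes so any stage can be rerun in isolation reproducibly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .deg_analysis import (
    deg_sets_vs_baseline,
    fuzzy_cmeans,
    standardize_profiles,
    test_deg_across_time,
)
from .dnb_core import DominantGroupConfig, permutation_test, scan_time_points
from .expression_io import (
    AnalysisConfig,
    ExpressionSeries,
    GeneNetwork,
    PathwayMap,
    read_edge_list,
    read_expression_matrix,
    read_gmt,
    write_expression_matrix,
)
from .prioritization import build_priority_table, rank_dnb_genes
from .subnet_dynamics import build_ranking, weight_proportions
from .synthetic_data import SimulationConfig, SimulationTruth, simulate_all

logger = logging.getLogger("dnbtip")

__all__ = ["PipelineError", "run_pipeline", "evaluate_against_truth", "stage_seed"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception | str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


def _load_config(config_path) -> dict:
    with open(config_path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if cfg.get("schema", 1) != 1:
        raise PipelineError("config", f"unsupported schema {cfg.get('schema')!r}")
    return cfg


def evaluate_against_truth(report: dict, truth: SimulationTruth) -> dict:
    """Recovery metrics of a report against the generator's ground truth."""
    detected = set(report.get("tipping_group", []))
    planted = set(truth.dnb_genes)
    union = detected | planted
    jaccard = len(detected & planted) / len(union) if union else 0.0
    ranks = {r["gene"]: r["rank"] for r in report.get("priority_table", [])}
    return {
        "tipping_hit": report.get("tipping") == truth.tipping_time,
        "dnb_jaccard": jaccard,
        "top_gene_rank": ranks.get(truth.top_gene),
    }


def run_pipeline(config_path) -> dict:
    """Run every stage described by the YAML config; return the report dict.

    All stage outputs are written under ``out_dir``; the report itself is
    saved as ``report.json``.  Deterministic given the config's seed.
    """
    cfg = _load_config(config_path)
    seed = int(cfg.get("seed", 0))
    out_dir = Path(cfg.get("out_dir", "dnbtip_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    analysis = AnalysisConfig(**cfg.get("analysis", {}))
    report: dict = {"schema": 1, "config": cfg, "outputs": {}}

    # ---- inputs (simulated or read from disk) ----------------------------
    truth: SimulationTruth | None = None
    network: GeneNetwork | None = None
    pathways: PathwayMap | None = None
    if cfg.get("simulate", False):
        try:
            sim_cfg = SimulationConfig(
                seed=stage_seed(seed, "simulate"), **cfg.get("simulation", {})
            )
            series, network, pathways, truth = simulate_all(sim_cfg)
        except Exception as exc:  # noqa: BLE001 - reported with stage name
            raise PipelineError("simulate", exc) from exc
        expr_path = out_dir / "expr.tsv"
        write_expression_matrix(series, expr_path)
        (out_dir / "network.tsv").write_text(
            "".join(f"{a}\t{b}\n" for a, b in sorted(network.edges)), encoding="utf-8"
        )
        (out_dir / "pathways.gmt").write_text(
            "".join(
                f"{p}\t{pathways.descriptions.get(p, '')}\t"
                + "\t".join(sorted(genes))
                + "\n"
                for p, genes in pathways.pathways.items()
            ),
            encoding="utf-8",
        )
        (out_dir / "truth.json").write_text(
            json.dumps(dataclasses.asdict(truth), indent=2), encoding="utf-8"
        )
        report["outputs"]["expression"] = str(expr_path)
        report["outputs"]["truth"] = str(out_dir / "truth.json")
    else:
        inputs = cfg.get("inputs", {})
        if "expression" not in inputs:
            raise PipelineError(
                "inputs", "config key 'inputs.expression' is required when simulate: false"
            )
        try:
            series = read_expression_matrix(inputs["expression"])
            if inputs.get("network"):
                network = read_edge_list(inputs["network"])
            if inputs.get("pathways"):
                pathways = read_gmt(inputs["pathways"])
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("inputs", exc) from exc

    # ---- DEG screening and clustering ------------------------------------
    try:
        deg = test_deg_across_time(series, fdr_threshold=analysis.fdr_threshold)
        comparisons = deg_sets_vs_baseline(
            series, baseline=analysis.baseline_time, fdr_threshold=analysis.fdr_threshold
        )
        deg_genes = sorted(deg.deg_genes)
        clusters = None
        if len(deg_genes) >= analysis.cluster_count:
            profiles = standardize_profiles(series, deg_genes)
            if len(profiles) >= analysis.cluster_count:
                clusters = fuzzy_cmeans(
                    profiles,
                    c=analysis.cluster_count,
                    m=analysis.fuzzifier,
                    seed=stage_seed(seed, "cluster"),
                )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("deg", exc) from exc
    deg.table.to_csv(out_dir / "deg_results.tsv", sep="\t")
    if clusters is not None:
        pd.DataFrame(
            {
                "gene": clusters.genes,
                "cluster": clusters.hard_labels,
                **{
                    f"m{j + 1}": clusters.membership[:, j]
                    for j in range(clusters.c)
                },
            }
        ).to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
    upset = pd.DataFrame(
        [
            {
                "comparison": lab,
                "set_size": len(genes),
                **{
                    f"int_{other}": n
                    for (a, b), n in comparisons.pairwise.items()
                    for other in ((b,) if a == lab else (a,) if b == lab else ())
                },
            }
            for lab, genes in comparisons.sets.items()
        ]
    )
    upset.to_csv(out_dir / "upset.tsv", sep="\t", index=False)
    report["outputs"]["deg_results"] = str(out_dir / "deg_results.tsv")
    report["n_deg"] = len(deg_genes)
    report["smallest_overlap_comparison"] = comparisons.smallest_overlap

    # ---- DNB scan ---------------------------------------------------------
    try:
        group_cfg = DominantGroupConfig(
            min_group_size=analysis.min_group_size,
            sd_fold=analysis.sd_fold,
            linkage_cut=analysis.linkage_cut,
            epsilon=analysis.epsilon,
            baseline_time=analysis.baseline_time,
        )
        dnb = scan_time_points(series, group_cfg)
        n_perm = int(cfg.get("permutations", 0))
        p_value = None
        if n_perm:
            p_value = permutation_test(
                series, group_cfg, n_perm=n_perm, seed=stage_seed(seed, "permutation")
            )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("dnb", exc) from exc
    ci_rows = []
    for t in series.times:
        comp = dnb.components.get(t)
        ci_rows.append(
            {
                "t": t,
                "N": comp.n if comp else 0,
                "SD_i": comp.sd_in if comp else np.nan,
                "PCC_i": comp.pcc_in if comp else np.nan,
                "PCC_o": comp.pcc_out if comp else np.nan,
                "CI": dnb.ci_series[t],
                "members": ";".join(comp.members) if comp else "",
            }
        )
    pd.DataFrame(ci_rows).to_csv(out_dir / "ci_series.tsv", sep="\t", index=False)
    report["outputs"]["ci_series"] = str(out_dir / "ci_series.tsv")
    report["ci_series"] = {str(t): dnb.ci_series[t] for t in series.times}
    report["tipping"] = dnb.tipping
    report["tipping_group"] = dnb.tipping_group
    report["permutation_p"] = p_value
    report["dnb_flags"] = dnb.flags

    # ---- prioritization ---------------------------------------------------
    table = []
    if dnb.tipping_group and network is not None and pathways is not None:
        try:
            records = build_priority_table(
                dnb.tipping_group, network, deg, clusters, pathways
            )
            ranked = rank_dnb_genes(records, mode=cfg.get("ranking_mode", "lexicographic"))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("prioritize", exc) from exc
        table = [dataclasses.asdict(r) for r in ranked]
        pd.DataFrame(table).to_csv(out_dir / "priority_table.tsv", sep="\t", index=False)
        report["outputs"]["priority_table"] = str(out_dir / "priority_table.tsv")
    report["priority_table"] = table

    # ---- focal-gene subnet -------------------------------------------------
    focal = cfg.get("focal_gene") or (table[0]["gene"] if table else None)
    if focal is not None and dnb.tipping is not None:
        try:
            ranking = build_ranking(series, focal, k=int(cfg.get("top_k", 20)))
            months = [t for t in (dnb.tipping - 1, dnb.tipping) if t in series.times]
            top10 = [g for g, _ in ranking.overall[:10]]
            weights = weight_proportions(series, focal, top10, months)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("subnet", exc) from exc
        pd.DataFrame(
            [{"gene": g, "mean_rank": s} for g, s in ranking.overall]
        ).to_csv(out_dir / "focal_ranking.tsv", sep="\t", index=False)
        weights.shares.rename("share").to_csv(out_dir / "weights.tsv", sep="\t")
        report["focal_gene"] = focal
        report["focal_top"] = ranking.overall
        report["weight_months"] = months
        report["weight_shares"] = {g: float(v) for g, v in weights.shares.items()}

    # ---- recovery metrics + report ----------------------------------------
    if truth is not None:
        report["recovery"] = evaluate_against_truth(report, truth)
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True), encoding="utf-8")
    report["outputs"]["report"] = str(report_path)
    return report
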