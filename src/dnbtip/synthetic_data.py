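"""Synthetic time-course expression with a planted critical transition.

The generator emulates the study design this pipeline targets: T monthly
time points with r replicate animals each, a small module of genes whose
per-gene standard deviation inflates and whose mutual correlation rises
sharply at a planted tipping time while its correlation to the background
drops, plus background differentially expressed genes (DEGs) whose mean
shifts are concentrated at an early (down) and a mid (up) time point.  A
consistent random network and pathway annotation are generated so that the
downstream prioritization criteria have a planted, recoverable answer.

Samples at each time point are drawn from a multivariate normal whose
covariance is built block-wise from the module parameters; modelling the
transition directly through the covariance gives exact control over the
three signatures the detector looks for (SD inflation, intra-module
correlation rise, module-background decorrelation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .expression_io import ExpressionSeries, GeneNetwork, PathwayMap

logger = logging.getLogger("dnbtip")

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "build_covariance",
    "simulate_series",
    "simulate_network",
    "simulate_pathways",
    "simulate_all",
]


@dataclass
class SimulationConfig:
    """Parameters of the planted-transition generator.

    Expression values are on a log2-like scale.  Defaults reflect the
    targeted study design: 500 genes, a 10-gene module, 8 monthly time
    points with 4 replicates each, tipping at month 6, a 3-fold SD
    inflation at the tipping point, intra-module correlation 0.2 -> 0.8
    and module-background correlation 0.2 -> 0.02.
    """

    n_genes: int = 500
    n_dnb: int = 10
    n_times: int = 8
    n_reps: int = 4
    tipping_time: int = 6
    sigma0: float = 1.0
    sd_fold: float = 3.0
    rho_in: float = 0.2
    rho_in_tip: float = 0.8
    rho_out: float = 0.2
    rho_out_tip: float = 0.02
    n_coupled_background: int = 5
    n_deg: int = 100
    deg_shift: float = 2.0
    deg_down_time: int = 2
    deg_up_time: int = 6
    baseline_mean: float = 8.0
    edge_prob: float = 0.04
    deg_enrich_top: float = 0.9
    deg_enrich_dnb: float = 0.3
    n_pathways: int = 50
    pathway_size_min: int = 10
    pathway_size_max: int = 40
    extra_pathways_top: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_dnb < self.n_genes:
            raise ValueError("need 2 <= n_dnb < n_genes")
        if not 1 <= self.tipping_time <= self.n_times:
            raise ValueError("tipping_time must lie in 1..n_times")
        if self.n_reps < 2:
            raise ValueError("need >=2 replicates per time point")
        if self.sd_fold < 1:
            raise ValueError("sd_fold must be >= 1")
        for rho in (self.rho_in, self.rho_in_tip, self.rho_out, self.rho_out_tip):
            if not abs(rho) < 1:
                raise ValueError("correlations must satisfy |rho| < 1")
        if self.n_deg > self.n_genes - self.n_dnb:
            raise ValueError("too many background DEGs for the gene count")
        if not 0 <= self.n_coupled_background <= self.n_genes - self.n_dnb:
            raise ValueError("n_coupled_background must fit in the background")
        if not 0 <= self.deg_enrich_dnb <= 1 or not 0 <= self.deg_enrich_top <= 1:
            raise ValueError("enrichment probabilities must lie in [0, 1]")
        if self.deg_enrich_dnb >= self.deg_enrich_top:
            raise ValueError("deg_enrich_top must exceed deg_enrich_dnb")

    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass
class SimulationTruth:
    """Ground truth of a simulated data set, for recovery checks."""

    dnb_genes: list[str]
    top_gene: str
    tipping_time: int
    deg_genes: dict[str, str]  # gene -> template pattern label
    cov_params: dict = field(default_factory=dict)


class ConfigurationError(ValueError):
    """Raised when generator parameters cannot yield a valid covariance."""


def _nearest_psd(cov: np.ndarray, tol: float = 1e-10, max_iter: int = 200) -> np.ndarray:
    """Project ``cov`` to the PSD cone, preserving the diagonal.

    Alternates eigenvalue clipping with restoration of the original
    variances; the per-gene variances drive the SD-based detector and must
    survive the repair exactly.
    """
    diag = np.diag(cov).copy()
    if np.any(diag < 0):
        raise ConfigurationError("negative variances requested")
    out = cov.copy()
    for _ in range(max_iter):
        w, v = np.linalg.eigh(out)
        if w.min() >= -tol:
            return out
        w = np.clip(w, 0.0, None)
        out = (v * w) @ v.T
        # restore variances (zero-variance rows stay zero)
        d = np.diag(out).copy()
        scale = np.ones_like(d)
        nz = (d > 0) & (diag > 0)
        scale[nz] = np.sqrt(diag[nz] / d[nz])
        out = out * np.outer(scale, scale)
        np.fill_diagonal(out, diag)
    w = np.linalg.eigvalsh(out)
    if w.min() < -1e-6:
        raise ConfigurationError(
            f"covariance not PSD-repairable (min eigenvalue {w.min():.3g})"
        )
    return out


_COV_CACHE: dict[tuple, np.ndarray] = {}


def build_covariance(t: int, config: SimulationConfig) -> np.ndarray:
    """Per-time covariance over all genes (module block first).

    Off the tipping time the module has variance ``sigma0**2`` with
    intra-module correlation ``rho_in`` and module-background correlation
    ``rho_out``; at ``tipping_time`` the module SD is multiplied by
    ``sd_fold``, intra-module correlation becomes ``rho_in_tip`` and the
    module-background correlation drops to ``rho_out_tip``.  Background
    genes are mutually independent with variance ``sigma0**2``.

    ``rho_out`` couples the module to the *last* ``n_coupled_background``
    genes only: a correlated module cannot be correlated at 0.2 with
    hundreds of mutually independent genes (the full block matrix is far
    from PSD, and projecting it back would manufacture background
    co-fluctuation, contradicting the independent-background design).
    Should a user configuration still be indefinite, it is projected to
    the nearest PSD matrix with the variances held fixed, and the repair
    is logged.
    """
    if not 1 <= t <= config.n_times:
        raise ValueError(f"time {t} outside 1..{config.n_times}")
    at_tip = t == config.tipping_time
    key = (
        at_tip,
        config.n_genes,
        config.n_dnb,
        config.n_coupled_background,
        config.sigma0,
        config.sd_fold,
        config.rho_in,
        config.rho_in_tip,
        config.rho_out,
        config.rho_out_tip,
    )
    cached = _COV_CACHE.get(key)
    if cached is not None:
        return cached.copy()

    k, n = config.n_dnb, config.n_genes
    sigma = config.sigma0 * (config.sd_fold if at_tip else 1.0)
    rho_in = config.rho_in_tip if at_tip else config.rho_in
    rho_out = config.rho_out_tip if at_tip else config.rho_out

    cov = np.zeros((n, n))
    cov[:k, :k] = rho_in * sigma**2
    ncb = config.n_coupled_background
    if ncb > 0:
        cov[:k, n - ncb :] = rho_out * sigma * config.sigma0
        cov[n - ncb :, :k] = cov[:k, n - ncb :].T
    np.fill_diagonal(cov, config.sigma0**2)
    cov[np.arange(k), np.arange(k)] = sigma**2

    if config.sigma0 == 0.0:
        _COV_CACHE[key] = cov
        return cov.copy()
    w_min = np.linalg.eigvalsh(cov).min()
    if w_min < -1e-10:
        logger.warning(
            "covariance at t=%d indefinite (min eigenvalue %.3g); applying PSD repair",
            t,
            w_min,
        )
        cov = _nearest_psd(cov)
    _COV_CACHE[key] = cov
    return cov.copy()


def _deg_templates(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Mean-shift templates over time, one per DEG pattern label."""
    down = np.zeros(config.n_times)
    down[config.deg_down_time - 1] = -config.deg_shift
    up = np.zeros(config.n_times)
    up[config.deg_up_time - 1] = config.deg_shift
    return {"down_early": down, "up_mid": up}


def simulate_series(config: SimulationConfig) -> tuple[ExpressionSeries, SimulationTruth]:
    """Draw a full time-course data set and return it with its ground truth.

    For each time point, ``n_reps`` samples are drawn from a multivariate
    normal with mean ``baseline_mean`` plus the DEG template shift and
    covariance :func:`build_covariance`.  Deterministic given the seed.
    """
    rng = np.random.default_rng([config.seed, 0])
    genes = config.gene_ids()
    k = config.n_dnb
    dnb_genes = genes[:k]
    deg_genes_list = genes[k : k + config.n_deg]
    templates = _deg_templates(config)
    labels = sorted(templates)
    deg_genes = {g: labels[i % len(labels)] for i, g in enumerate(deg_genes_list)}

    mean_shift = np.zeros((config.n_genes, config.n_times))
    for i, g in enumerate(deg_genes_list, start=k):
        mean_shift[i, :] = templates[deg_genes[g]]

    chol: dict[bool, np.ndarray | None] = {}
    for at_tip in {t == config.tipping_time for t in range(1, config.n_times + 1)}:
        t_rep = config.tipping_time if at_tip else (1 if config.tipping_time != 1 else 2)
        cov = build_covariance(t_rep, config)
        if not cov.any():
            chol[at_tip] = None  # degenerate zero-noise mode
        else:
            w, v = np.linalg.eigh(cov)
            chol[at_tip] = v * np.sqrt(np.clip(w, 0.0, None))

    cols = []
    sample_labels = []
    time_of: dict[str, int] = {}
    rep_of: dict[str, int] = {}
    for t in range(1, config.n_times + 1):
        mean = config.baseline_mean + mean_shift[:, t - 1]
        factor = chol[t == config.tipping_time]
        for j in range(1, config.n_reps + 1):
            if factor is None:
                x = mean.copy()
            else:
                x = mean + factor @ rng.standard_normal(config.n_genes)
            label = f"M{t}_R{j}"
            sample_labels.append(label)
            time_of[label] = t
            rep_of[label] = j
            cols.append(x)
    values = np.column_stack(cols)

    series = ExpressionSeries(genes, sample_labels, time_of, rep_of, values)
    truth = SimulationTruth(
        dnb_genes=dnb_genes,
        top_gene=dnb_genes[0],
        tipping_time=config.tipping_time,
        deg_genes=deg_genes,
        cov_params={
            "sigma0": config.sigma0,
            "sd_fold": config.sd_fold,
            "rho_in": config.rho_in,
            "rho_in_tip": config.rho_in_tip,
            "rho_out": config.rho_out,
            "rho_out_tip": config.rho_out_tip,
        },
    )
    return series, truth


def simulate_network(truth: SimulationTruth, config: SimulationConfig) -> GeneNetwork:
    """Random background network with planted DEG-neighbor enrichment.

    The planted top gene's neighborhood is resampled so each neighbor is a
    DEG with probability ``deg_enrich_top``; other module genes get the
    strictly lower ``deg_enrich_dnb``.  Background wiring is Erdos-Renyi
    with ``edge_prob``.
    """
    rng = np.random.default_rng([config.seed, 1])
    genes = config.gene_ids()
    graph = nx.fast_gnp_random_graph(
        len(genes), config.edge_prob, seed=int(rng.integers(2**31))
    )
    graph = nx.relabel_nodes(graph, dict(enumerate(genes)))

    deg_set = set(truth.deg_genes)
    non_deg = [g for g in genes if g not in deg_set]
    expected_degree = max(4, round(config.edge_prob * (len(genes) - 1)))

    for gene, enrich in [(truth.top_gene, config.deg_enrich_top)] + [
        (g, config.deg_enrich_dnb) for g in truth.dnb_genes if g != truth.top_gene
    ]:
        degree = max(graph.degree(gene), expected_degree)
        graph.remove_edges_from(list(graph.edges(gene)))
        n_deg_nb = rng.binomial(degree, enrich)
        deg_pool = [g for g in deg_set if g != gene]
        other_pool = [g for g in non_deg if g != gene]
        picks = list(rng.choice(deg_pool, size=min(n_deg_nb, len(deg_pool)), replace=False))
        picks += list(
            rng.choice(other_pool, size=min(degree - len(picks), len(other_pool)), replace=False)
        )
        graph.add_edges_from((gene, nb) for nb in picks)

    return GeneNetwork(
        nodes=set(genes),
        edges={tuple(sorted(e)) for e in graph.edges()},
    )


def simulate_pathways(truth: SimulationTruth, config: SimulationConfig) -> PathwayMap:
    """Random pathways; the planted top gene gets strictly the most memberships."""
    rng = np.random.default_rng([config.seed, 2])
    genes = config.gene_ids()
    if config.n_pathways == 0:
        return PathwayMap(pathways={})
    pathways: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for i in range(1, config.n_pathways + 1):
        size = int(
            rng.integers(config.pathway_size_min, config.pathway_size_max + 1)
        )
        members = set(rng.choice(genes, size=min(size, len(genes)), replace=False))
        name = f"PW{i:03d}"
        pathways[name] = members
        descriptions[name] = f"synthetic pathway {i}"

    top = truth.top_gene
    others = [g for g in truth.dnb_genes if g != top]
    # extra memberships for the planted top gene, then enforce strictness
    absent = [p for p in pathways if top not in pathways[p]]
    rng.shuffle(absent)
    for p in absent[: config.extra_pathways_top]:
        pathways[p].add(top)

    def count(g: str) -> int:
        return sum(1 for m in pathways.values() if g in m)

    max_other = max((count(g) for g in others), default=-1)
    absent = [p for p in pathways if top not in pathways[p]]
    rng.shuffle(absent)
    while count(top) <= max_other and absent:
        pathways[absent.pop()].add(top)
    if others and count(top) <= max(count(g) for g in others):
        # every pathway already contains the top gene; thin a competitor
        for g in others:
            while count(g) >= count(top):
                p = next(p for p in pathways if g in pathways[p] and len(pathways[p]) > 1)
                pathways[p].discard(g)
    return PathwayMap(pathways=pathways, descriptions=descriptions)


def simulate_all(
    config: SimulationConfig,
) -> tuple[ExpressionSeries, GeneNetwork, PathwayMap, SimulationTruth]:
    """Convenience wrapper: series, network and pathways from one config."""
    series, truth = simulate_series(config)
    network = simulate_network(truth, config)
    pathways = simulate_pathways(truth, config)
    return series, network, pathways, truth
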