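"""Consensus co-expression networks and the composite convergence score.

The network-convergence score for a gene network is the sum of four terms:
mean local clustering coefficient (Cp), the path term max(Lp) - Lp against
the longest average shortest-path length in the scored collection, the mean
over gene pairs of the summed MF + BP + CC semantic similarities, and the
edge-duplication ratio (minimum per-edge duplication count over the number
of reconstruction runs).

The consensus builder is a correlation-bootstrap stand-in for a sparse
Bayesian bi-clustering reconstruction: it reproduces the two properties the
score consumes — co-expression edges and their per-edge duplication counts
across resampled runs — and is pluggable for higher-fidelity builders.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class GeneNetwork:
    """Undirected simple graph with per-edge duplication counts over runs."""

    graph: nx.Graph
    n_runs: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("self-loops are not allowed")
        for u, v, d in self.graph.edges(data=True):
            c = d.get("duplication_count")
            if c is None or not (1 <= c <= self.n_runs):
                raise ValueError(
                    f"edge ({u}, {v}) duplication_count must be in [1, n_runs]"
                )

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def min_duplication(self) -> int | None:
        counts = [d["duplication_count"] for _, _, d in self.graph.edges(data=True)]
        return min(counts) if counts else None

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_a": u, "gene_b": v, "duplication_count": d["duplication_count"],
             "n_runs": self.n_runs}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "duplication_count", "n_runs"])


def build_consensus_network(
    expr: pd.DataFrame,
    genes=None,
    n_runs: int = 40,
    builder: str = "corr_bootstrap",
    corr_min: float = 0.8,
    dup_min: float = 0.5,
    seed: int | None = None,
) -> GeneNetwork:
    """Bootstrap-consensus co-expression network.

    Parameters
    ----------
    expr
        samples x genes expression pooled across the knockout subset and
        controls (>= 10 samples recommended).
    genes
        Optional restriction to the responsive gene subset.
    n_runs
        Number of bootstrap resamples.
    corr_min
        Absolute Pearson correlation threshold for an edge within a run.
    dup_min
        Minimum duplication fraction (count / n_runs) for the consensus.
    """
    if builder != "corr_bootstrap":
        raise ValueError(f"unknown builder {builder!r}")
    if genes is not None:
        expr = expr.loc[:, list(genes)]
    n_samples, n_genes = expr.shape
    if n_samples < 10:
        logger.warning("fewer than 10 samples pooled; consensus may be unstable")
    rng = np.random.default_rng(seed)
    x = expr.to_numpy(float)
    gene_ids = list(expr.columns)

    counts = np.zeros((n_genes, n_genes), dtype=int)
    for _ in range(n_runs):
        idx = rng.integers(0, n_samples, size=n_samples)
        xb = x[idx]
        sd = xb.std(axis=0)
        ok = sd > 0
        corr = np.zeros((n_genes, n_genes))
        if ok.sum() >= 2:
            sub = np.corrcoef(xb[:, ok], rowvar=False)
            corr[np.ix_(ok, ok)] = sub
        np.fill_diagonal(corr, 0.0)
        counts += (np.abs(corr) >= corr_min).astype(int)

    g = nx.Graph()
    g.add_nodes_from(gene_ids)
    thr = dup_min * n_runs
    iu, ju = np.triu_indices(n_genes, k=1)
    for i, j in zip(iu, ju):
        if counts[i, j] >= thr and counts[i, j] >= 1:
            g.add_edge(gene_ids[i], gene_ids[j], duplication_count=int(counts[i, j]))
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
    if g.number_of_edges() == 0:
        logger.warning("no edges survived the consensus; network is unscorable")
    meta = {"builder": builder, "corr_min": corr_min, "dup_min": dup_min, "seed": seed}
    return GeneNetwork(graph=g, n_runs=n_runs, metadata=meta)


def clustering_coefficient(net: GeneNetwork | nx.Graph) -> float:
    """Mean local clustering coefficient; degree-<2 nodes contribute 0."""
    g = net.graph if isinstance(net, GeneNetwork) else net
    if g.number_of_nodes() == 0:
        raise ValueError("network has no nodes")
    return float(nx.average_clustering(g))


def avg_path_length(net: GeneNetwork | nx.Graph) -> float:
    """Mean shortest-path length over connected ordered pairs.

    Disconnected pairs are excluded (their count is logged); NaN when no
    pair is connected.
    """
    g = net.graph if isinstance(net, GeneNetwork) else net
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("need >= 2 nodes")
    total = 0
    used = 0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        for target, d in lengths.items():
            if d > 0:
                total += d
                used += 1
    all_pairs = n * (n - 1)
    if used < all_pairs:
        logger.info("%d of %d ordered pairs disconnected", all_pairs - used, all_pairs)
    if used == 0:
        return float("nan")
    return total / used


@dataclass
class NetworkScoreBreakdown:
    """Composite network-convergence score and its four components."""

    cp: float
    lp: float
    max_lp: float
    path_term: float
    semsim_mean: float
    dup_ratio: float
    total: float


def network_convergence_score(
    net: GeneNetwork,
    collection_max_lp: float | None,
    semsim_scores: dict | None,
) -> NetworkScoreBreakdown:
    """Composite score: Cp + (max Lp - Lp) + mean pairwise semsim + dup ratio.

    Parameters
    ----------
    collection_max_lp
        Largest average path length among the networks scored together; a
        single-network collection passes None (path term 0).  Clipped up to
        this network's Lp if smaller (logged).
    semsim_scores
        Unordered gene pair -> (mf, bp, cc) similarity triple.  The semsim
        term is the mean over the network's node pairs of the triple sum;
        missing pairs count 0.  ``None`` sets the term to 0.
    """
    if net.n_edges == 0:
        raise ValueError("empty network is unscorable")
    cp = clustering_coefficient(net)
    lp = avg_path_length(net)
    if collection_max_lp is None or np.isnan(lp):
        max_lp = lp
    else:
        max_lp = collection_max_lp
        if max_lp < lp:
            logger.warning("collection_max_lp < Lp; clipping to Lp")
            max_lp = lp
    path_term = 0.0 if np.isnan(lp) else max_lp - lp

    nodes = sorted(net.graph.nodes)
    if semsim_scores and len(nodes) >= 2:
        sums = []
        for a, b in itertools.combinations(nodes, 2):
            triple = semsim_scores.get((a, b)) or semsim_scores.get((b, a)) or (0, 0, 0)
            sums.append(float(sum(triple)))
        semsim_mean = float(np.mean(sums))
    else:
        semsim_mean = 0.0

    dup = net.min_duplication()
    dup_ratio = dup / net.n_runs if dup is not None else 0.0
    total = cp + path_term + semsim_mean + dup_ratio
    return NetworkScoreBreakdown(
        cp=cp, lp=lp, max_lp=max_lp, path_term=path_term,
        semsim_mean=semsim_mean, dup_ratio=dup_ratio, total=total,
    )
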