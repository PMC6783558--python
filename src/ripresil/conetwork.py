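"""Co-occurrence networks from thresholded Spearman correlations.

Nodes are taxa (typically genera); an edge joins taxa i and j when the
Spearman rank correlation of their relative abundances across samples is
both strong (|rho| > rho_min, default 0.6) and significant (p < p_max,
default 0.01) — strict inequalities on both thresholds.  Edges keep the
correlation as a signed weight.  Topology summaries report node/edge
counts, average degree (avgK = 2E/N), average path length and diameter on
the largest connected component, mean local clustering, and Louvain
modularity on the sign-ignored unweighted graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import CompositionTable, CountTable, parse_lineage, relative_abundance

__all__ = [
    "CorrelationMatrices",
    "CooccurrenceNetwork",
    "TopologySummary",
    "spearman_matrix",
    "filter_network_taxa",
    "build_network",
    "topology_summary",
    "export_network",
]


@dataclass
class CorrelationMatrices:
    """Pairwise Spearman rho and two-sided p over taxa (symmetric)."""

    taxon_ids: list[str]
    rho: np.ndarray
    p: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        m = len(self.taxon_ids)
        if self.rho.shape != (m, m) or self.p.shape != (m, m):
            raise ValueError("correlation matrices must be square over taxa")


@dataclass
class CooccurrenceNetwork:
    """Undirected signed-edge graph over taxa with the thresholds used."""

    graph: nx.Graph
    rho_min: float
    p_max: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    def drop_isolated(self) -> "CooccurrenceNetwork":
        """Copy of the network restricted to nodes with at least one edge."""
        keep = [n for n, d in self.graph.degree if d > 0]
        return CooccurrenceNetwork(self.graph.subgraph(keep).copy(),
                                   self.rho_min, self.p_max)


@dataclass(frozen=True)
class TopologySummary:
    n_nodes: int
    n_edges: int
    n_positive_edges: int
    n_negative_edges: int
    average_degree: float
    average_path_length: float
    diameter: float
    clustering_coefficient: float
    modularity: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def spearman_matrix(composition: CompositionTable) -> CorrelationMatrices:
    """All-pairs Spearman correlations of taxa across samples.

    Average ranks on ties; rho is the Pearson correlation of the rank
    vectors; two-sided p from the t approximation on n-2 degrees of
    freedom.  Taxa constant across samples have undefined correlations and
    are reported as NaN with a warning.
    """
    x = composition.proportions.to_numpy(dtype=float)
    m, n = x.shape
    if n < 5:
        raise ValueError("need at least 5 samples for correlation inference")
    if m < 2:
        raise ValueError("need at least 2 taxa")

    ranks = np.vstack([stats.rankdata(row) for row in x])
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        names = [composition.taxon_ids[i] for i in np.flatnonzero(constant)]
        warnings.warn(
            f"taxa constant across samples have undefined correlations: {names}",
            stacklevel=2,
        )

    centred = ranks - ranks.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = centred @ centred.T / n
        rho = cov / np.outer(sd, sd)
    rho = np.clip(rho, -1.0, 1.0)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan

    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1.0] = 0.0
    p[np.isnan(rho)] = np.nan

    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    return CorrelationMatrices(
        taxon_ids=list(composition.taxon_ids), rho=rho, p=p, n_samples=n
    )


def filter_network_taxa(
    table: CountTable,
    min_prevalence: float = 1.0 / 3.0,
    min_mean_abundance: float = 0.0,
) -> CountTable:
    """Keep taxa detected in >= ``min_prevalence`` of samples with mean
    relative abundance >= ``min_mean_abundance``."""
    if not (0 <= min_prevalence <= 1 and 0 <= min_mean_abundance <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    counts = table.counts
    prevalence = (counts > 0).mean(axis=1)
    mean_abund = relative_abundance(table).proportions.mean(axis=1)
    keep = (prevalence >= min_prevalence) & (mean_abund >= min_mean_abundance)
    if not keep.any():
        raise ValueError(
            "no taxa pass the prevalence/abundance filter; relax the thresholds"
        )
    return CountTable(counts.loc[keep].copy(), table.taxonomy)


def build_network(
    corr: CorrelationMatrices,
    rho_min: float = 0.6,
    p_max: float = 0.01,
    taxonomy: pd.Series | None = None,
) -> CooccurrenceNetwork:
    """Threshold correlations into a signed co-occurrence graph.

    Edge (i, j) exists iff |rho_ij| > rho_min AND p_ij < p_max (strict).
    All taxa stay in the node set; nodes without edges carry
    ``isolated=True``.  Node attribute ``phylum`` is filled from the
    taxonomy lineage when available.
    """
    if not (0 <= rho_min <= 1) or not (0 <= p_max <= 1):
        raise ValueError("thresholds out of range")
    g = nx.Graph()
    for taxon in corr.taxon_ids:
        phylum = ""
        if taxonomy is not None and taxon in taxonomy.index:
            parts = parse_lineage(taxonomy.loc[taxon])
            if len(parts) > 1:
                phylum = parts[1]
        g.add_node(taxon, phylum=phylum)

    m = len(corr.taxon_ids)
    for i in range(m):
        for j in range(i + 1, m):
            r, p = corr.rho[i, j], corr.p[i, j]
            if np.isnan(r) or np.isnan(p):
                continue
            if abs(r) > rho_min and p < p_max:
                g.add_edge(
                    corr.taxon_ids[i],
                    corr.taxon_ids[j],
                    rho=float(r),
                    p=float(p),
                    sign=1 if r > 0 else -1,
                )
    for node, degree in g.degree:
        g.nodes[node]["degree"] = degree
        g.nodes[node]["isolated"] = degree == 0
    return CooccurrenceNetwork(graph=g, rho_min=rho_min, p_max=p_max)


def topology_summary(net: CooccurrenceNetwork, modularity_seed: int = 0) -> TopologySummary:
    """Topology statistics of a co-occurrence network.

    Path length and diameter are computed on the largest connected
    component of the unweighted graph (thresholded networks are often
    disconnected); clustering is the mean local coefficient with
    degree < 2 nodes contributing 0; modularity is the Louvain Q on the
    sign-ignored unweighted graph with a fixed seed.  Path statistics and
    modularity are NaN for edgeless networks.
    """
    g = net.graph
    n_nodes = g.number_of_nodes()
    if n_nodes == 0:
        raise ValueError("cannot summarise an empty (zero-node) network")
    n_edges = g.number_of_edges()
    signs = [d.get("sign", 1) for _, _, d in g.edges(data=True)]
    n_pos = sum(1 for s in signs if s > 0)
    n_neg = n_edges - n_pos

    if n_edges == 0:
        return TopologySummary(
            n_nodes=n_nodes, n_edges=0, n_positive_edges=0, n_negative_edges=0,
            average_degree=0.0, average_path_length=float("nan"),
            diameter=float("nan"), clustering_coefficient=0.0,
            modularity=float("nan"),
        )

    avg_k = 2.0 * n_edges / n_nodes
    components = list(nx.connected_components(g))
    giant = g.subgraph(max(components, key=len))
    if giant.number_of_nodes() > 1:
        apl = nx.average_shortest_path_length(giant)
        diam = float(nx.diameter(giant))
    else:
        apl, diam = float("nan"), float("nan")
    clustering = nx.average_clustering(g)  # degree < 2 contributes 0
    communities = nx.community.louvain_communities(g, seed=modularity_seed, weight=None)
    q = nx.community.modularity(g, communities, weight=None)
    return TopologySummary(
        n_nodes=n_nodes,
        n_edges=n_edges,
        n_positive_edges=n_pos,
        n_negative_edges=n_neg,
        average_degree=avg_k,
        average_path_length=float(apl),
        diameter=diam,
        clustering_coefficient=float(clustering),
        modularity=float(q),
    )


def export_network(net: CooccurrenceNetwork, path, format: str = "gexf") -> None:
    """Write the network as GEXF, GraphML, or a TSV edge list.

    Node attributes (phylum, degree) and edge attributes (rho, p, sign)
    are preserved in the XML formats; the edge list has columns
    taxon_a, taxon_b, rho, p, sign.
    """
    if format == "gexf":
        nx.write_gexf(net.graph, path)
    elif format == "graphml":
        nx.write_graphml(net.graph, path)
    elif format == "edge_tsv":
        rows = [
            {"taxon_a": a, "taxon_b": b, "rho": d["rho"], "p": d["p"], "sign": d["sign"]}
            for a, b, d in net.graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "p", "sign"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown export format {format!r}; "
                         "use gexf, graphml or edge_tsv")
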