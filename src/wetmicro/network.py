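"""Correlation-based co-occurrence networks and their topology.

Builds a taxon co-occurrence graph from pairwise rank correlations
(Spearman by default, |rho| >= 0.6 and BH-adjusted p <= 0.05, taxa
present in at least a third of samples) and reports the topology row a
network table prints: node/edge counts, signed-link percentages,
modularity (seeded Louvain), mean local clustering, average degree
(2E/N) and mean shortest-path length on the largest component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import AbundanceTable

__all__ = ["CorrelationNetwork", "TopologyReport", "build_network", "topology"]


@dataclass
class CorrelationNetwork:
    """Signed correlation graph plus the parameters that built it."""

    graph: nx.Graph
    params: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "rho": d["rho"], "sign": d["sign"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "rho", "sign"])

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


@dataclass
class TopologyReport:
    """One row of network topology indices (percentages sum to 100)."""

    nodes: int
    edges: int
    positive_pct: float
    negative_pct: float
    modularity: float
    avg_clustering: float
    avg_degree: float
    avg_path_distance: float
    largest_component_fraction: float = 1.0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def build_network(table: AbundanceTable, method: str = "spearman",
                  rho_min: float = 0.6, p_max: float = 0.05, fdr: bool = True,
                  min_prevalence: float = 1 / 3) -> CorrelationNetwork:
    """Co-occurrence network from pairwise taxon correlations.

    Taxa below the prevalence filter or with constant abundance are
    dropped (constants with a warning; their correlation is undefined).
    An edge is kept when |rho| >= ``rho_min`` and the (BH-adjusted when
    ``fdr``) p-value is <= ``p_max``; the edge sign is sign(rho).
    """
    if table.n_samples < 5:
        raise ValueError("need at least 5 samples for correlation networks")
    filtered = table.filter_prevalence(min_prevalence)
    x = filtered.counts
    const = x.columns[x.nunique(axis=0) <= 1]
    if len(const):
        warnings.warn(f"dropping {len(const)} constant taxa (correlation undefined)")
        x = x.drop(columns=const)
    if x.shape[1] < 2:
        raise ValueError("fewer than 2 taxa survive the filters")

    if method == "spearman":
        rho, pval = stats.spearmanr(x.to_numpy())
        if np.ndim(rho) == 0:  # scipy collapses the 2-taxon case to a scalar
            rho = np.array([[1.0, rho], [rho, 1.0]])
            pval = np.array([[0.0, pval], [pval, 0.0]])
    elif method == "pearson":
        arr = x.to_numpy()
        nt = arr.shape[1]
        rho = np.corrcoef(arr, rowvar=False)
        # t-test p-values for Pearson r
        n = arr.shape[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
        pval = 2 * stats.t.sf(np.abs(t), df=n - 2)
        np.fill_diagonal(pval, 0.0)
    else:
        raise ValueError(f"unknown correlation method {method!r}")

    taxa = list(x.columns)
    iu = np.triu_indices(len(taxa), k=1)
    rho_flat = rho[iu]
    p_flat = pval[iu]
    if fdr:
        p_adj = multipletests(p_flat, method="fdr_bh")[1]
    else:
        p_adj = p_flat
    keep = (np.abs(rho_flat) >= rho_min) & (p_adj <= p_max)

    g = nx.Graph()
    g.add_nodes_from(taxa)
    for (i, j, r) in zip(iu[0][keep], iu[1][keep], rho_flat[keep]):
        g.add_edge(taxa[i], taxa[j], rho=float(r), sign=int(np.sign(r)))
    params = {"method": method, "rho_min": rho_min, "p_max": p_max,
              "fdr": "benjamini-hochberg" if fdr else "none",
              "min_prevalence": min_prevalence}
    return CorrelationNetwork(graph=g, params=params)


def topology(network: CorrelationNetwork | nx.Graph, seed: int = 0) -> TopologyReport:
    """Topology indices of a co-occurrence network.

    Average degree is exactly 2E/N; clustering is the mean local
    clustering coefficient (degree < 2 nodes contribute 0); the average
    path distance is the unweighted mean shortest path over the largest
    connected component; modularity comes from a seeded Louvain partition
    of the unsigned graph.
    """
    g = network.graph if isinstance(network, CorrelationNetwork) else network
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        warnings.warn("empty network: returning a degenerate report")
        return TopologyReport(0, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    signs = [d.get("sign", 1) for _, _, d in g.edges(data=True)]
    pos = sum(1 for s in signs if s > 0)
    pos_pct = 100.0 * pos / e if e else 0.0
    neg_pct = 100.0 - pos_pct if e else 0.0
    avg_degree = 2.0 * e / n
    avg_clust = float(np.mean(list(nx.clustering(g).values()))) if n else 0.0
    if e:
        comp = max(nx.connected_components(g), key=len)
        sub = g.subgraph(comp)
        apd = (nx.average_shortest_path_length(sub)
               if sub.number_of_nodes() > 1 else 0.0)
        comp_frac = sub.number_of_nodes() / n
        communities = nx.community.louvain_communities(g, seed=seed)
        mod = nx.community.modularity(g, communities)
    else:
        apd, comp_frac, mod = 0.0, 0.0, 0.0
    return TopologyReport(
        nodes=n, edges=e, positive_pct=pos_pct, negative_pct=neg_pct,
        modularity=float(mod), avg_clustering=avg_clust,
        avg_degree=avg_degree, avg_path_distance=float(apd),
        largest_component_fraction=float(comp_frac),
    )
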