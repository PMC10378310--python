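"""Node centralities and the per-node feature table.

Nine classical centralities describe each node's structural position:

===== =======================================================================
K     degree — number of one-hop neighbours
Ksum  one-hop neighbourhood — sum of neighbours' degrees
K2sum two-hop neighbourhood — sum of degrees over nodes within two hops
KS    k-shell (coreness) index from iterative degree pruning
C     local clustering coefficient, 2E(i)/(K(i)(K(i)−1))
B     shortest-path betweenness (raw counts, endpoints excluded)
CC    closeness, (N−1)/Σ_j d_ij
EC    eigenvector centrality (leading eigenvector, unit Euclidean norm)
PR    PageRank, PR(i) = α Σ_j A_ij PR(j)/K(j) + β with β = (1−α)/N
===== =======================================================================

The feature table drops columns that are constant across nodes (zero
discriminative value for a classifier); on BA preferential-attachment graphs
the k-shell index is degenerate — every node sits in shell m — so KS is
removed there, leaving eight features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .netgen import Network

#: Canonical column order; also the tie-break order used throughout selection.
TABLE_ORDER: tuple[str, ...] = ("K", "Ksum", "K2sum", "KS", "C", "B", "CC", "EC", "PR")

__all__ = ["TABLE_ORDER", "CentralityConfig", "FeatureTable", "kshell", "two_hop_sum",
           "compute_feature_table", "canonical_sort"]


def canonical_sort(names) -> list[str]:
    """Sort feature names by the canonical column order (unknown names last)."""
    order = {name: i for i, name in enumerate(TABLE_ORDER)}
    return sorted(names, key=lambda f: (order.get(f, len(TABLE_ORDER)), f))


@dataclass
class CentralityConfig:
    """Numerical settings for the centrality computations.

    ``pr_damping`` is the PageRank damping factor α; the per-node teleport
    constant is (1−α)/N.  ``exact_two_hop`` switches K2sum from the default
    within-two-hops neighbourhood (distance 1 or 2) to the exactly-distance-2
    shell.  Columns with variance strictly below ``constancy_tol`` are
    dropped; 0 disables dropping.
    """

    pr_damping: float = 0.85
    eig_tol: float = 1e-10
    eig_max_iter: int = 10_000
    constancy_tol: float = 1e-12
    exact_two_hop: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.pr_damping < 1.0:
            raise ValueError("pr_damping must be in (0, 1)")
        if self.eig_tol <= 0 or self.constancy_tol < 0:
            raise ValueError("tolerances must be non-negative")


@dataclass
class FeatureTable:
    """N×d matrix of centrality values, one row per node.

    ``values`` is a DataFrame indexed by node id with columns in canonical
    order; ``dropped`` lists centralities removed for being constant.
    """

    values: pd.DataFrame
    dropped: list[str] = field(default_factory=list)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_nodes(self) -> int:
        return len(self.values)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="node_id")


def kshell(net: Network) -> np.ndarray:
    """K-shell (coreness) index per node, via iterative degree pruning."""
    core = nx.core_number(net.graph)
    return np.array([core[i] for i in range(net.n_nodes)])


def two_hop_sum(net: Network, node: int, exact: bool = False) -> float:
    """Sum of degrees over the two-hop neighbourhood of *node*.

    By default the neighbourhood is all nodes at shortest-path distance 1 or
    2 (the node itself excluded); with ``exact=True`` only distance-2 nodes
    are counted.
    """
    g = net.graph
    if node not in g:
        raise ValueError(f"unknown node {node}")
    dist = nx.single_source_shortest_path_length(g, node, cutoff=2)
    wanted = (2,) if exact else (1, 2)
    return float(sum(g.degree(j) for j, d in dist.items() if d in wanted))


def compute_feature_table(net: Network, cfg: CentralityConfig | None = None) -> FeatureTable:
    """Compute all nine centralities for every node of a connected network.

    Returns a :class:`FeatureTable` with constant columns removed (recorded
    in ``dropped``).  Betweenness is left as raw path counts — the scale is
    irrelevant after the per-feature standardisation applied by every
    downstream classifier — and closeness uses the (N−1)/Σd convention, so
    CC ∈ (0, 1] on connected graphs.
    """
    cfg = cfg or CentralityConfig()
    g = net.graph
    n = net.n_nodes
    if not nx.is_connected(g):
        raise ValueError("feature table requires a connected network (closeness undefined)")
    nodes = range(n)

    deg = dict(g.degree())
    k = np.array([deg[i] for i in nodes], dtype=float)
    ksum = np.array([sum(deg[j] for j in g[i]) for i in nodes], dtype=float)
    k2sum = np.array([two_hop_sum(net, i, exact=cfg.exact_two_hop) for i in nodes])
    ks = kshell(net).astype(float)
    clus = nx.clustering(g)
    c = np.array([clus[i] for i in nodes])
    btw = nx.betweenness_centrality(g, normalized=False)
    b = np.array([btw[i] for i in nodes])
    clo = nx.closeness_centrality(g)
    cc = np.array([clo[i] for i in nodes])
    try:
        eig = nx.eigenvector_centrality(g, max_iter=cfg.eig_max_iter, tol=cfg.eig_tol)
        ec = np.abs(np.array([eig[i] for i in nodes]))
    except nx.PowerIterationFailedConvergence:
        # bipartite-like spectra (eigenvalues ±λ1) defeat power iteration;
        # take the leading eigenvector from a dense symmetric eigensolver
        A = nx.to_numpy_array(g, nodelist=list(nodes))
        w, v = np.linalg.eigh(A)
        ec = np.abs(v[:, int(np.argmax(w))])
    ec /= np.linalg.norm(ec)
    pr_d = nx.pagerank(g, alpha=cfg.pr_damping, tol=1e-12, max_iter=1000)
    pr = np.array([pr_d[i] for i in nodes])

    df = pd.DataFrame(
        {"K": k, "Ksum": ksum, "K2sum": k2sum, "KS": ks, "C": c,
         "B": b, "CC": cc, "EC": ec, "PR": pr},
        index=pd.Index(nodes, name="node_id"),
    )
    variances = df.var(ddof=0)
    dropped = [col for col in df.columns if variances[col] < cfg.constancy_tol]
    return FeatureTable(values=df.drop(columns=dropped), dropped=dropped)
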