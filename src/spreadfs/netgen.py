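"""Synthetic network generation and edge-list input/output.

Three classical random-graph models are supported — Barabási–Albert (BA)
preferential attachment, Erdős–Rényi (ER) random graphs and Watts–Strogatz
(WS) small-world networks — together with a plain-text edge-list format for
real-world networks.  All emitted networks are simple, undirected, connected
graphs with dense integer node ids ``0..n-1``, which is what the epidemic
simulator and the path-based centralities downstream require.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "GeneratorSpec",
    "generate_ba",
    "generate_er",
    "generate_ws",
    "from_spec",
    "read_edgelist",
    "write_edgelist",
    "validate_network",
]


@dataclass
class Network:
    """An undirected simple connected graph with node ids ``0..n-1``.

    Attributes
    ----------
    graph
        The underlying :class:`networkx.Graph`.
    name
        Free-text label recording provenance (model, parameters, seed).
    original_labels
        For graphs loaded from edge lists: dense id -> original token.
    """

    graph: nx.Graph
    name: str = ""
    original_labels: dict[int, str] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def edges(self) -> set[tuple[int, int]]:
        return {(min(u, v), max(u, v)) for u, v in self.graph.edges()}

    @property
    def density(self) -> float:
        return nx.density(self.graph)


def validate_network(net: Network) -> None:
    """Raise ``ValueError`` unless *net* satisfies the structural invariants.

    Checks dense 0-based ids, no self-loops (duplicate edges are impossible
    in a ``networkx.Graph``), and connectedness.
    """
    g = net.graph
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    if set(g.nodes()) != set(range(n)):
        raise ValueError("node ids must be exactly 0..n-1")
    if any(u == v for u, v in g.edges()):
        raise ValueError("self-loops are not allowed")
    if not nx.is_connected(g):
        raise ValueError("network must be connected")


@dataclass
class GeneratorSpec:
    """Parameters of one synthetic-network draw.

    ``avg_degree`` is the target mean degree ⟨k⟩; for BA it is translated to
    the attachment count m = round(avg_degree / 2), for WS it is the ring
    degree (must be even).  ``rewire_p`` only applies to WS.
    """

    model: str  # "BA" | "ER" | "WS"
    n: int = 1000
    avg_degree: float = 6.0
    rewire_p: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("BA", "ER", "WS"):
            raise ValueError(f"unknown model {self.model!r}")
        if not 0 < self.avg_degree < self.n:
            raise ValueError("avg_degree must be in (0, n)")
        if not 0.0 <= self.rewire_p <= 1.0:
            raise ValueError("rewire_p must be in [0, 1]")
        if self.model == "WS" and int(self.avg_degree) % 2 != 0:
            raise ValueError("WS ring construction needs an even avg_degree")


def generate_ba(n: int, m: int, seed: int, max_tries: int = 100) -> Network:
    """Barabási–Albert preferential-attachment graph.

    Growth starts from m isolated nodes; each of the remaining n−m arriving
    nodes attaches m edges to distinct existing nodes with probability
    proportional to current degree, so the final edge count is exactly
    m·(n−m) — e.g. 2991 edges at n=1000, m=3.

    Draws are conditioned on minimum degree ≥ m: occasionally one of the m
    zero-degree seed nodes never attracts further attachments and ends with
    degree < m, breaking the uniform k-shell index (= m) that characterises
    the model; such rare draws are regenerated with ``seed+1, seed+2, …``.
    """
    if m < 1 or m >= n:
        raise ValueError("require 1 <= m < n")
    for attempt in range(max_tries):
        g = nx.barabasi_albert_graph(n, m, seed=seed + attempt)
        if min(d for _, d in g.degree()) >= m:
            net = Network(g, name=f"BA(n={n},m={m},seed={seed + attempt})")
            validate_network(net)
            return net
    raise RuntimeError(f"no BA draw with min degree >= {m} in {max_tries} tries")


def generate_er(n: int, avg_degree: float, seed: int) -> Network:
    """Erdős–Rényi G(n, p) graph with p = avg_degree/(n−1).

    A sparse G(n, p) draw is almost never connected in full, so the largest
    connected component is extracted and re-indexed to dense ids; at ⟨k⟩=6
    it covers essentially all nodes.  The realised size is recorded in the
    network name.
    """
    if avg_degree <= 0 or avg_degree >= n:
        raise ValueError("require 0 < avg_degree < n")
    p = avg_degree / (n - 1)
    g = nx.gnp_random_graph(n, p, seed=seed)
    if g.number_of_edges() == 0:
        raise ValueError("generated graph has no edges (avg_degree too small)")
    giant = max(nx.connected_components(g), key=len)
    g = g.subgraph(giant).copy()
    g = nx.convert_node_labels_to_integers(g, ordering="sorted")
    net = Network(g, name=f"ER(n={n},lcc={g.number_of_nodes()},k={avg_degree},seed={seed})")
    validate_network(net)
    return net


def generate_ws(n: int, k: int, rewire_p: float, seed: int, max_tries: int = 100) -> Network:
    """Watts–Strogatz small-world graph (ring degree k, rewiring rewire_p).

    Rewiring preserves the edge count n·k/2 but can occasionally disconnect
    the graph; disconnected draws are regenerated with ``seed+1, seed+2, …``
    until connected.
    """
    if k % 2 != 0:
        raise ValueError("ring degree k must be even")
    if k >= n:
        raise ValueError("require k < n")
    for attempt in range(max_tries):
        g = nx.watts_strogatz_graph(n, k, rewire_p, seed=seed + attempt)
        if nx.is_connected(g):
            net = Network(g, name=f"WS(n={n},k={k},p={rewire_p},seed={seed + attempt})")
            validate_network(net)
            return net
    raise RuntimeError(f"no connected WS draw in {max_tries} tries")


def from_spec(spec: GeneratorSpec) -> Network:
    """Generate a network from a :class:`GeneratorSpec`."""
    if spec.model == "BA":
        m = max(1, round(spec.avg_degree / 2))
        return generate_ba(spec.n, m, spec.seed)
    if spec.model == "ER":
        return generate_er(spec.n, spec.avg_degree, spec.seed)
    return generate_ws(spec.n, int(spec.avg_degree), spec.rewire_p, spec.seed)


def read_edgelist(path: str | Path) -> Network:
    """Read a whitespace-separated edge list into a :class:`Network`.

    Lines starting with ``#`` are comments.  Node tokens are mapped to dense
    0-based ids in first-appearance order; self-loops and duplicate edges are
    dropped with a logged count.  The graph is restricted to its largest
    connected component if disconnected.
    """
    path = Path(path)
    g = nx.Graph()
    dropped_self = dropped_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ValueError(f"{path}:{lineno}: expected two node tokens, got {line!r}")
            a, b = tokens[0], tokens[1]
            if a == b:
                dropped_self += 1
                continue
            if g.has_edge(a, b):
                dropped_dup += 1
                continue
            g.add_edge(a, b)
    if dropped_self or dropped_dup:
        logger.warning(
            "%s: dropped %d self-loop and %d duplicate rows", path, dropped_self, dropped_dup
        )
    if g.number_of_nodes() == 0:
        raise ValueError(f"{path}: no edges found")
    if not nx.is_connected(g):
        giant = max(nx.connected_components(g), key=len)
        logger.warning(
            "%s: disconnected (%d nodes); keeping largest component (%d nodes)",
            path, g.number_of_nodes(), len(giant),
        )
        g = g.subgraph(giant).copy()
    # dense 0-based ids, numeric-aware so 0-based numeric files round-trip
    def sort_key(tok: str):
        return (0, int(tok), tok) if tok.lstrip("-").isdigit() else (1, 0, tok)
    ordered = sorted(g.nodes(), key=sort_key)
    mapping = {tok: i for i, tok in enumerate(ordered)}
    g = nx.relabel_nodes(g, mapping)
    net = Network(g, name=path.stem,
                  original_labels={i: tok for tok, i in mapping.items()})
    validate_network(net)
    return net


def write_edgelist(net: Network, path: str | Path) -> None:
    """Write one ``u v`` line per edge, 0-based, sorted by (u, v)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {net.name}: {net.n_nodes} nodes, {net.n_edges} edges\n")
        for u, v in sorted(net.edges):
            fh.write(f"{u} {v}\n")
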