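"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: betweenness is counted
by enumerating shortest paths pair by pair, and the SIR outcome distribution
is computed by exhaustive branching over infection events (feasible for
graphs with a handful of nodes and recovery probability 1).
"""

from itertools import chain, combinations

import networkx as nx


def brute_betweenness(g: nx.Graph) -> dict:
    """Unnormalised betweenness by explicit shortest-path enumeration."""
    b = {v: 0.0 for v in g}
    for s, t in combinations(g.nodes(), 2):
        paths = list(nx.all_shortest_paths(g, s, t))
        for v in g:
            if v in (s, t):
                continue
            b[v] += sum(v in p for p in paths) / len(paths)
    return b


def _subsets(items):
    items = list(items)
    return chain.from_iterable(combinations(items, r) for r in range(len(items) + 1))


def exact_sir_mean(g: nx.Graph, seed_node, beta: float) -> float:
    """Exact E[ρ] of synchronous SIR with μ=1 by exhaustive branching.

    State = (frontier, recovered); each susceptible node with m infectious
    neighbours becomes infected next step with probability 1 − (1−β)^m,
    independently across nodes.  All infectious nodes recover (μ=1).
    """
    n = g.number_of_nodes()

    def expand(frontier: frozenset, recovered: frozenset) -> float:
        """Expected final recovered count given the current state."""
        if not frontier:
            return len(recovered)
        at_risk = {}
        for v in set().union(*(set(g[u]) for u in frontier)):
            if v in frontier or v in recovered:
                continue
            m = sum(v in g[u] for u in frontier)
            at_risk[v] = 1.0 - (1.0 - beta) ** m
        new_recovered = recovered | frontier
        total = 0.0
        for hit in _subsets(at_risk):
            p = 1.0
            for v, pv in at_risk.items():
                p *= pv if v in hit else (1.0 - pv)
            if p > 0.0:
                total += p * expand(frozenset(hit), new_recovered)
        return total

    return expand(frozenset([seed_node]), frozenset()) / n
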