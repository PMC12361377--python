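"""Hypergeometric co-occurrence networks and metabolic-guild clustering.

Functions (pathways) that co-occur across genomes more often than expected
under random placement form the edges of a co-occurrence network.  For a
pair of functions present in n_A and n_B of N genomes with k joint
occurrences, significance is the upper hypergeometric tail
P[X >= k], X ~ Hypergeometric(N, n_A, n_B), computed by exact summation in
log space.  Each p is scaled to an E-value (expected number of false edges)
by the number of pairs tested; edges with E below the threshold (default
0.1) are retained.

The retained network is partitioned into metabolic guilds by edge-clustering-
coefficient agglomeration: edges are merged in descending
ECC(u,v) = (z(u,v) + 1) / min(deg u - 1, deg v - 1)   (z = shared neighbours)
order and the partition with maximum modularity along the merge sequence is
returned.  Tie-breaks are lexicographic on the edge id, so the partition is
deterministic.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)

__all__ = ["CooccurrenceEdge", "GuildNetwork", "hypergeom_tail",
           "build_network", "cluster_guilds"]


def _log_comb(n: int, k: int) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_tail(N: int, n_a: int, n_b: int, k: int) -> float:
    """Exact upper tail P[X >= k] for X ~ Hypergeometric(N, n_a, n_b).

    X counts the overlap when n_b items are drawn without replacement from a
    population of N containing n_a marked items.  Summation is done on
    log-probabilities for numerical stability.
    """
    for name, v in (("N", N), ("n_a", n_a), ("n_b", n_b)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if n_a > N or n_b > N:
        raise ValueError("marginals cannot exceed N")
    lo = max(0, n_a + n_b - N)
    hi = min(n_a, n_b)
    if k < 0 or k > hi:
        raise ValueError(f"joint count k={k} inconsistent with marginals")
    if k <= lo:
        return 1.0
    denom = _log_comb(N, n_b)
    terms = [
        _log_comb(n_a, j) + _log_comb(N - n_a, n_b - j) - denom
        for j in range(k, hi + 1)
    ]
    return float(min(1.0, math.exp(logsumexp(terms))))


@dataclass(frozen=True)
class CooccurrenceEdge:
    function_a: str
    function_b: str
    n_genomes: int
    n_a: int
    n_b: int
    joint: int
    p_value: float
    e_value: float
    retained: bool


@dataclass
class GuildNetwork:
    """Co-occurrence network with node weights and guild partition.

    ``graph`` holds only the retained edges; ``edges`` records every tested
    pair.  ``partition`` (function id -> guild id) is filled by
    :func:`cluster_guilds`; nodes with no retained edge stay unassigned.
    """

    graph: nx.Graph
    edges: pd.DataFrame
    e_threshold: float
    multiplicity: int
    node_weights: dict[str, float] = field(default_factory=dict)
    partition: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "e_threshold": self.e_threshold,
            "multiplicity": self.multiplicity,
            "nodes": [
                {
                    "id": n,
                    "weight": self.node_weights.get(n),
                    "guild": self.partition.get(n),
                }
                for n in sorted(self.graph.nodes)
            ],
            "edges": [
                {"source": u, "target": v, **{k: d[k] for k in ("p", "e", "k")}}
                for u, v, d in sorted(self.graph.edges(data=True))
            ],
        }


def build_network(
    matrix: pd.DataFrame,
    proportions: pd.Series | None = None,
    e_threshold: float = 0.1,
    multiplicity: str = "pairs",
) -> GuildNetwork:
    """Test all unordered function pairs for co-occurrence across genomes.

    ``matrix`` is the genome x function detection-count (or boolean) matrix;
    presence is ``value >= 1``.  ``multiplicity="pairs"`` multiplies p by the
    number of pairs tested (Bonferroni-style E-value); ``"none"`` uses the
    raw p as the E-value.  ``proportions`` (function id -> corrected
    proportion) become node weights.
    """
    if matrix.shape[1] < 1:
        raise ValueError("at least one function column is required")
    presence = (matrix >= 1).astype(bool)
    n_genomes = presence.shape[0]
    functions = list(presence.columns)
    marginals = presence.sum(axis=0)
    for f in functions:
        if marginals[f] in (0, n_genomes):
            logger.info("function %s has degenerate marginal %d/%d "
                        "(kept, can never be significant)",
                        f, int(marginals[f]), n_genomes)

    pairs = list(itertools.combinations(functions, 2))
    m = len(pairs) if multiplicity == "pairs" else 1
    if multiplicity not in ("pairs", "none"):
        raise ValueError(f"unknown multiplicity {multiplicity!r}")

    graph = nx.Graph()
    graph.add_nodes_from(functions)
    rows = []
    values = presence.to_numpy()
    col = {f: i for i, f in enumerate(functions)}
    for a, b in pairs:
        n_a = int(marginals[a])
        n_b = int(marginals[b])
        k = int(np.sum(values[:, col[a]] & values[:, col[b]]))
        p = hypergeom_tail(n_genomes, n_a, n_b, k)
        e = p * m
        retained = e < e_threshold
        rows.append(CooccurrenceEdge(a, b, n_genomes, n_a, n_b, k, p, e,
                                     retained))
        if retained:
            graph.add_edge(a, b, p=p, e=e, k=k)

    edges = pd.DataFrame([r.__dict__ for r in rows])
    weights = {} if proportions is None else {
        f: float(proportions[f]) for f in functions if f in proportions
    }
    for f in functions:
        if f in weights:
            graph.nodes[f]["weight"] = weights[f]
    return GuildNetwork(graph=graph, edges=edges, e_threshold=e_threshold,
                        multiplicity=m, node_weights=weights)


def _ecc(graph: nx.Graph, u: str, v: str) -> float:
    """Edge clustering coefficient with the +1 triangle pseudo-count."""
    z = len(set(graph[u]) & set(graph[v]))
    d = min(graph.degree(u) - 1, graph.degree(v) - 1)
    if d <= 0:
        return math.inf      # bridge to a degree-1 node: always merge first
    return (z + 1) / d


def cluster_guilds(network: GuildNetwork, method: str = "ecc") -> dict[str, str]:
    """Partition the retained network into guilds.

    ``method="ecc"`` (default) agglomerates along the deterministic
    ECC-descending edge sequence, returning the partition of maximum
    modularity; ``method="greedy"`` uses plain greedy modularity
    agglomeration as a cross-check.  Nodes with at least one retained edge
    are covered; isolated nodes are left unassigned.
    """
    graph = network.graph
    active = [n for n in graph.nodes if graph.degree(n) > 0]
    sub = graph.subgraph(active)
    if sub.number_of_edges() == 0:
        network.partition = {}
        return {}

    if method == "greedy":
        communities = nx.algorithms.community.greedy_modularity_communities(sub)
    elif method == "ecc":
        order = sorted(
            sub.edges(),
            key=lambda e: (-_ecc(sub, *e), tuple(sorted(e))),
        )
        parent = {n: n for n in sub.nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def groups():
            out: dict[str, set] = {}
            for n in sub.nodes:
                out.setdefault(find(n), set()).add(n)
            return list(out.values())

        best = groups()
        best_q = nx.algorithms.community.modularity(sub, best)
        for u, v in order:
            ru, rv = find(u), find(v)
            if ru == rv:
                continue
            parent[max(ru, rv)] = min(ru, rv)
            parts = groups()
            q = nx.algorithms.community.modularity(sub, parts)
            if q > best_q:
                best_q = q
                best = parts
        communities = best
    else:
        raise ValueError(f"unknown method {method!r}")

    ordered = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    partition = {
        node: f"guild_{i + 1}" for i, members in enumerate(ordered)
        for node in members
    }
    network.partition = partition
    return partition
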