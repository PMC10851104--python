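"""Topological analysis: maximal cliques, MCC, coefficients, hubs.

Maximal Clique Centrality of a node v is

    MCC(v) = sum over maximal cliques C containing v of (|C| - 1)!

applied literally: an isolated node lies in its own singleton maximal
clique and scores 0! = 1.  Hubs are called either by an MCC threshold
(default >= 4) or as the top-N nodes by MCC with lexicographic
tie-breaking, since fixed hub counts are also reported in practice.

The topological coefficient follows the NetworkAnalyzer convention:
T(n) = avg_m J(n, m) / k(n) over nodes m != n sharing at least one
neighbor with n, where J(n, m) is the number of shared neighbors plus one
when n and m are directly adjacent.
"""

from __future__ import annotations

from math import factorial

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from histonet.exceptions import DegenerateDegreeError
from histonet.networks import Network


def _as_graph(network) -> nx.Graph:
    if isinstance(network, Network):
        return network.graph
    return network


def enumerate_maximal_cliques(network) -> list[frozenset]:
    """All maximal cliques, each once (Bron–Kerbosch with pivoting)."""
    graph = _as_graph(network)
    return [frozenset(c) for c in nx.find_cliques(graph)]


def mcc_score(network, node, cliques: list[frozenset] | None = None) -> int:
    """MCC(v) = Σ_{C ∋ v} (|C|−1)! over maximal cliques; exact integer."""
    graph = _as_graph(network)
    if node not in graph:
        raise KeyError(f"node {node!r} not in network")
    if cliques is None:
        cliques = enumerate_maximal_cliques(graph)
    return sum(factorial(len(c) - 1) for c in cliques if node in c)


def mcc_scores(network) -> dict:
    graph = _as_graph(network)
    cliques = enumerate_maximal_cliques(graph)
    scores = {n: 0 for n in graph.nodes}
    for clique in cliques:
        contribution = factorial(len(clique) - 1)
        for node in clique:
            scores[node] += contribution
    return scores


def clustering_coefficient(network, node=None):
    """C = 2 e_N / (k (k−1)); 0 when the node has fewer than two neighbors."""
    graph = _as_graph(network)
    if node is not None:
        return nx.clustering(graph, node)
    return nx.clustering(graph)


def topological_coefficient(network, node=None):
    """NetworkAnalyzer-style topological coefficient (see module docstring).

    Nodes with no co-neighbor partners (or degree 0) report 0.0.
    """
    graph = _as_graph(network)
    if node is not None:
        return _topological_one(graph, node)
    return {n: _topological_one(graph, n) for n in graph.nodes}


def _topological_one(graph: nx.Graph, node) -> float:
    k = graph.degree(node)
    if k == 0:
        return 0.0
    neighbors = set(graph[node])
    partners: dict = {}
    for nb in neighbors:
        for m in graph[nb]:
            if m == node:
                continue
            partners[m] = partners.get(m, 0) + 1
    if not partners:
        return 0.0
    j_values = [
        shared + (1 if graph.has_edge(node, m) else 0)
        for m, shared in partners.items()
    ]
    return float(np.mean(j_values)) / k


def betweenness(network) -> dict:
    """Normalized shortest-path betweenness (Brandes), unweighted."""
    graph = _as_graph(network)
    return nx.betweenness_centrality(graph, normalized=True)


def identify_hubs(network, mcc_threshold: int = 4, top_n: int | None = None) -> list:
    """Hub nodes by MCC: threshold mode or fixed top-N (lexicographic ties)."""
    scores = mcc_scores(network)
    if top_n is not None:
        ranked = sorted(scores.items(), key=lambda kv: (-kv[1], str(kv[0])))
        return [n for n, _ in ranked[:top_n]]
    return sorted(
        (n for n, s in scores.items() if s >= mcc_threshold), key=str
    )


def powerlaw_decay_check(network, metric: str = "C") -> dict:
    """Log–log decay of per-degree mean clustering (C) or topological (T)
    coefficient versus degree.

    Returns the OLS slope of log(mean metric) on log(degree) and the
    Spearman correlation of the per-degree mean metric versus degree (the
    decay statistic; per-node correlations are dominated by the many
    low-degree nodes whose local clustering is exactly zero).
    Scale-free-like networks show a negative slope and negative rho.
    Requires at least 10 distinct degrees.
    """
    graph = _as_graph(network)
    if metric == "C":
        values = nx.clustering(graph)
    elif metric == "T":
        values = topological_coefficient(graph)
    else:
        raise ValueError("metric must be 'C' or 'T'")
    degrees = dict(graph.degree())
    distinct = sorted(set(degrees.values()))
    if len(distinct) < 10:
        raise DegenerateDegreeError(
            f"only {len(distinct)} distinct degrees; need >= 10"
        )
    per_degree: dict[int, list[float]] = {}
    for n, k in degrees.items():
        per_degree.setdefault(k, []).append(values[n])
    ks, means = [], []
    for k in distinct:
        if k == 0:
            continue
        mean = float(np.mean(per_degree[k]))
        if mean > 0:
            ks.append(k)
            means.append(mean)
    if len(ks) < 3:
        raise DegenerateDegreeError("too few positive per-degree means")
    slope = float(np.polyfit(np.log(ks), np.log(means), 1)[0])
    all_ks = [k for k in distinct if k > 0]
    all_means = [float(np.mean(per_degree[k])) for k in all_ks]
    rho = float(stats.spearmanr(all_ks, all_means).statistic)
    return {"slope": slope, "spearman_rho": rho}


def topology_report(network, mcc_threshold: int = 4) -> pd.DataFrame:
    """Per-node table: degree, C, T, betweenness, MCC, is_hub."""
    graph = _as_graph(network)
    c = nx.clustering(graph)
    t = topological_coefficient(graph)
    b = betweenness(graph)
    mcc = mcc_scores(graph)
    rows = [
        {
            "node_id": n,
            "degree": graph.degree(n),
            "clustering_coefficient": c[n],
            "topological_coefficient": t[n],
            "betweenness": b[n],
            "mcc": mcc[n],
            "is_hub": mcc[n] >= mcc_threshold,
        }
        for n in sorted(graph.nodes, key=str)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "node_id", "degree", "clustering_coefficient",
            "topological_coefficient", "betweenness", "mcc", "is_hub",
        ],
    )
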