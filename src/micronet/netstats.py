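"""Whole-network and per-node topological property tables.

Properties are computed on the unweighted skeleton (a ``weighted=True`` flag
switches shortest-path-based quantities to |r| weights).  Disconnected
graphs follow the igraph convention: path statistics average over
within-component ordered pairs only, never propagating infinities.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .netbuild import ModulePartition, modularity_q

EIG_TOL = 1e-10
EIG_MAX_ITER = 10_000

NET_PROPERTY_NAMES = [
    "num_nodes", "num_edges", "num_positive_edges", "num_negative_edges",
    "mean_degree", "density", "connectance", "diameter",
    "average_path_length", "transitivity", "average_local_clustering",
    "num_components", "edge_connectivity", "closeness_centralization",
    "betweenness_centralization", "modularity_Q",
]


def _path_stats(net: nx.Graph) -> tuple[float, float]:
    """(average_path_length, diameter) over finite within-component pairs."""
    total = 0.0
    count = 0
    diam = 0.0
    for source, dists in nx.all_pairs_shortest_path_length(net):
        for target, d in dists.items():
            if target == source:
                continue
            total += d
            count += 1
            diam = max(diam, d)
    if count == 0:
        return 0.0, 0.0
    return total / count, diam


def closeness_centralization(net: nx.Graph) -> float:
    """Freeman centralization of (normalized) closeness; 1 for a star."""
    n = net.number_of_nodes()
    if n < 3:
        return 0.0
    c = nx.closeness_centrality(net)  # normalized, within-component
    cmax = max(c.values())
    num = sum(cmax - v for v in c.values())
    denom = (n - 2) * (n - 1) / (2 * n - 3)  # star-graph maximum
    return num / denom


def betweenness_centralization(net: nx.Graph) -> float:
    """Freeman centralization of normalized betweenness; 1 for a star."""
    n = net.number_of_nodes()
    if n < 3:
        return 0.0
    b = nx.betweenness_centrality(net, normalized=True)
    bmax = max(b.values())
    return sum(bmax - v for v in b.values()) / (n - 1)


def net_properties(net: nx.Graph, part=None) -> pd.Series:
    """Whole-network property table.

    Single-node (or edgeless) graphs report path-based properties as 0.
    Edge connectivity is computed on the largest connected component.
    """
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("network is empty")
    e = net.number_of_edges()
    signs = [d.get("sign", "positive" if d.get("r", 1.0) > 0 else "negative")
             for _, _, d in net.edges(data=True)]
    pos = sum(s == "positive" for s in signs)
    apl, diam = _path_stats(net)
    density = 0.0 if n < 2 else 2.0 * e / (n * (n - 1))
    if e > 0:
        giant = net.subgraph(max(nx.connected_components(net), key=len))
        ec = float(nx.edge_connectivity(giant)) if giant.number_of_nodes() > 1 else 0.0
    else:
        ec = 0.0
    q = np.nan
    if part is not None:
        q = part.Q if isinstance(part, ModulePartition) else modularity_q(net, part)
    vals = {
        "num_nodes": float(n),
        "num_edges": float(e),
        "num_positive_edges": float(pos),
        "num_negative_edges": float(e - pos),
        "mean_degree": 2.0 * e / n,
        "density": density,
        "connectance": density,  # identical for undirected simple graphs
        "diameter": diam,
        "average_path_length": apl,
        "transitivity": nx.transitivity(net) if n > 2 else 0.0,
        "average_local_clustering": nx.average_clustering(net) if n > 0 else 0.0,
        "num_components": float(nx.number_connected_components(net)),
        "edge_connectivity": ec,
        "closeness_centralization": closeness_centralization(net),
        "betweenness_centralization": betweenness_centralization(net),
        "modularity_Q": q,
    }
    return pd.Series(vals, name="value")[NET_PROPERTY_NAMES]


def eigenvector_centrality(net: nx.Graph) -> dict[str, float]:
    """Power-iteration eigenvector centrality, max-normalized to 1.

    Deterministic uniform start vector; tolerance 1e-10, at most 10^4
    iterations — non-convergence raises rather than returning silently.
    """
    nodes = list(net.nodes)
    n = len(nodes)
    if n == 0:
        return {}
    A = nx.to_numpy_array(net, nodelist=nodes, weight=None)
    if A.sum() == 0:
        return {v: 0.0 for v in nodes}
    x = np.full(n, 1.0 / n)
    for _ in range(EIG_MAX_ITER):
        # iterate with A + I: same dominant eigenvector, but convergent on
        # bipartite graphs whose +/-lambda pair stalls plain power iteration
        y = A @ x + x
        norm = np.linalg.norm(y)
        if norm == 0:
            return {v: 0.0 for v in nodes}
        y /= norm
        if np.abs(y - x).max() < EIG_TOL:
            x = y
            break
        x = y
    else:
        raise RuntimeError("eigenvector centrality power iteration "
                           "did not converge")
    x = x / x.max()
    return {v: float(val) for v, val in zip(nodes, x)}


def node_properties(net: nx.Graph, part=None) -> pd.DataFrame:
    """Per-node degree, closeness, betweenness, eigenvector centrality.

    Closeness for node i is reachable_i / sum of distances within i's
    component (isolated nodes get 0); betweenness is Brandes, normalized.
    """
    nodes = list(net.nodes)
    closeness = nx.closeness_centrality(net, wf_improved=False)
    betweenness = nx.betweenness_centrality(net, normalized=True)
    eig = eigenvector_centrality(net)
    mapping = {}
    if part is not None:
        mapping = part.mapping if isinstance(part, ModulePartition) else dict(part)
    df = pd.DataFrame({
        "degree": [net.degree[v] for v in nodes],
        "closeness": [closeness[v] for v in nodes],
        "betweenness": [betweenness[v] for v in nodes],
        "eigenvector": [eig[v] for v in nodes],
        "module": [mapping.get(v, "") for v in nodes],
    }, index=pd.Index(nodes, name="taxon"))
    return df
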