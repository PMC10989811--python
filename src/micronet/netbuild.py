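"""Graph construction and modularity-based module detection.

Edges retained by the correlation filter become an undirected signed simple
graph; communities ("modules") are found by greedy agglomerative modularity
maximization (Clauset-Newman-Moore) on the unweighted skeleton, matching the
fast-greedy family the field's network pipelines use.  Modules are labeled
``module_1, module_2, ...`` in decreasing size order (ties broken by the
lexicographically smallest member taxon).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import networkx as nx
import pandas as pd


@dataclasses.dataclass
class ModulePartition:
    """Node -> module-label mapping plus the modularity score Q."""

    mapping: dict[str, str]
    Q: float

    def __getitem__(self, node: str) -> str:
        return self.mapping[node]

    def __contains__(self, node: str) -> bool:
        return node in self.mapping

    def __iter__(self):
        return iter(self.mapping)

    def __len__(self) -> int:
        return len(self.mapping)

    def modules(self) -> dict[str, list[str]]:
        """Module label -> sorted member list, in label rank order."""
        out: dict[str, list[str]] = {}
        for node, lab in self.mapping.items():
            out.setdefault(lab, []).append(node)
        return {lab: sorted(out[lab]) for lab in sorted(out, key=_label_key)}

    def sizes(self) -> dict[str, int]:
        return {lab: len(members) for lab, members in self.modules().items()}


def _label_key(label: str):
    # module_10 sorts after module_2
    if label.startswith("module_") and label.split("_", 1)[1].isdigit():
        return (0, int(label.split("_", 1)[1]))
    return (1, label)


def build_graph(edges: pd.DataFrame, isolate_policy: str = "drop",
                nodes: Iterable[str] | None = None,
                node_attrs: pd.DataFrame | None = None) -> nx.Graph:
    """Build a simple undirected signed graph from an edge table.

    ``isolate_policy`` is ``drop`` (graph nodes are exactly the edge
    endpoints) or ``keep`` (also add the zero-degree taxa from ``nodes``).
    Listing the same unordered pair twice with equal r collapses to one
    edge; conflicting r values are an error.  ``node_attrs`` (indexed by
    taxon) may carry mean_abundance / group attributes.
    """
    if isolate_policy not in {"drop", "keep"}:
        raise ValueError(f"isolate_policy must be drop|keep, got {isolate_policy!r}")
    g = nx.Graph()
    if isolate_policy == "keep" and nodes is not None:
        g.add_nodes_from(nodes)
    for row in edges.itertuples(index=False):
        u, v, r = row.source, row.target, float(row.r)
        if g.has_edge(u, v):
            if abs(g[u][v]["r"] - r) > 1e-12:
                raise ValueError(
                    f"duplicate pair ({u}, {v}) with conflicting r")
            continue
        g.add_edge(u, v, r=r, p=float(getattr(row, "p", float("nan"))),
                   sign="positive" if r > 0 else "negative")
    if node_attrs is not None:
        for n in g.nodes:
            if n in node_attrs.index:
                for c in node_attrs.columns:
                    g.nodes[n][c] = node_attrs.loc[n, c]
    return g


def detect_modules(net: nx.Graph, weighted: bool = False) -> ModulePartition:
    """Greedy (CNM) modularity maximization.

    Runs on the unweighted skeleton by default; ``weighted=True`` uses |r|
    edge weights.  Zero-edge graphs put every node in its own module with
    Q = 0.  Singleton components become their own modules.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot detect modules on an empty graph")
    weight = None
    if weighted:
        for u, v, d in net.edges(data=True):
            d["abs_r"] = abs(d.get("r", 1.0))
        weight = "abs_r"
    if net.number_of_edges() == 0:
        communities = [{n} for n in net.nodes]
        Q = 0.0
    else:
        communities = [set(c) for c in nx.community.greedy_modularity_communities(
            net, weight=weight)]
        Q = nx.community.modularity(net, communities, weight=weight)
    return _rank_and_label(communities, Q)


def _rank_and_label(communities: list[set], Q: float) -> ModulePartition:
    ordered = sorted(communities,
                     key=lambda c: (-len(c), min(str(n) for n in c)))
    mapping = {}
    for k, comm in enumerate(ordered, start=1):
        for n in comm:
            mapping[n] = f"module_{k}"
    return ModulePartition(mapping=mapping, Q=float(Q))


def pool_small_modules(part: ModulePartition,
                       min_size: int = 1) -> ModulePartition:
    """Merge modules smaller than ``min_size`` into one ``module_other``.

    Remaining labels are re-ranked by size.  ``min_size=1`` is the identity.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    groups = part.modules()
    big = [set(m) for m in groups.values() if len(m) >= min_size]
    small = [n for m in groups.values() if len(m) < min_size for n in m]
    ordered = sorted(big, key=lambda c: (-len(c), min(str(n) for n in c)))
    mapping = {}
    for k, comm in enumerate(ordered, start=1):
        for n in comm:
            mapping[n] = f"module_{k}"
    for n in small:
        mapping[n] = "module_other"
    return ModulePartition(mapping=mapping, Q=part.Q)


def modularity_q(net: nx.Graph, part) -> float:
    """Q = sum_s [ l_s/L - (d_s/2L)^2 ] for a given labeling."""
    mapping = part.mapping if hasattr(part, "mapping") else dict(part)
    groups: dict[str, set] = {}
    for n, lab in mapping.items():
        groups.setdefault(lab, set()).add(n)
    return float(nx.community.modularity(net, list(groups.values())))
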