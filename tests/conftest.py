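"""Shared fixtures: small graphs with known structure and random tables."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from micronet import AbundanceTable, ModulePartition


@pytest.fixture
def two_triangles() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                      ("x", "y"), ("y", "z"), ("x", "z")])
    return g


@pytest.fixture
def star5() -> nx.Graph:
    """Star with center 'c' and 4 leaves (5 nodes)."""
    g = nx.Graph()
    g.add_edges_from([("c", f"l{i}") for i in range(4)])
    return g


@pytest.fixture
def three_module_net() -> tuple[nx.Graph, ModulePartition]:
    """Three cliques (8, 6, 4 nodes) joined by single bridges."""
    g = nx.Graph()
    blocks = [[f"a{i}" for i in range(8)], [f"b{i}" for i in range(6)],
              [f"c{i}" for i in range(4)]]
    mapping = {}
    for k, block in enumerate(blocks):
        for u in block:
            mapping[u] = f"module_{k + 1}"
        g.add_edges_from(
            (block[i], block[j]) for i in range(len(block))
            for j in range(i + 1, len(block)))
    g.add_edge("a0", "b0")
    g.add_edge("b1", "c0")
    return g, ModulePartition(mapping=mapping, Q=0.0)


@pytest.fixture
def random_table() -> AbundanceTable:
    rng = np.random.default_rng(42)
    vals = rng.poisson(50, size=(8, 20)).astype(float)
    return AbundanceTable(values=pd.DataFrame(
        vals, index=[f"t{i}" for i in range(8)],
        columns=[f"s{j}" for j in range(20)]))


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    g = nx.gnp_random_graph(n, p, seed=seed)
    return nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
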