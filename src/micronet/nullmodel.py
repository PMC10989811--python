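"""Erdős–Rényi null-model comparison.

Observed network topology is judged against an ensemble of G(n, m) random
graphs matched to the observed node and edge counts: for each property the
ensemble mean, standard deviation and the observed z-score are reported.
Matching m (rather than a probability p) removes edge-count variance from
the comparison.  A degree-preserving configuration-model ensemble is
available behind a flag.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd

from .netbuild import detect_modules
from .netstats import _path_stats

COMPARED_PROPERTIES = [
    "average_path_length", "diameter", "transitivity",
    "average_local_clustering", "modularity_Q",
]


@dataclasses.dataclass
class NullComparison:
    """Observed vs null-ensemble statistics per property."""

    table: pd.DataFrame  # rows: property; cols: observed, null_mean, null_sd, z
    n_replicates: int
    seed: int | None
    null_model: str = "erdos_renyi"


def er_random_graph(n: int, m: int, seed=None) -> nx.Graph:
    """G(n, m): m distinct unordered pairs sampled uniformly at random."""
    npairs = n * (n - 1) // 2
    if not 0 <= m <= npairs:
        raise ValueError(f"m must be in [0, {npairs}] for n={n}, got {m}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    chosen = rng.choice(npairs, size=m, replace=False)
    iu, ju = np.triu_indices(n, k=1)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(zip(iu[chosen].tolist(), ju[chosen].tolist()))
    return g


def _properties(g: nx.Graph) -> dict[str, float]:
    apl, diam = _path_stats(g)
    part = detect_modules(g)
    return {
        "average_path_length": apl,
        "diameter": diam,
        "transitivity": nx.transitivity(g),
        "average_local_clustering": nx.average_clustering(g),
        "modularity_Q": part.Q,
    }


def compare_to_random(net: nx.Graph, part=None, n_reps: int = 100,
                      seed: int | None = None,
                      null_model: str = "erdos_renyi") -> NullComparison:
    """Compare a network's properties to a matched random-graph ensemble.

    Generates ``n_reps`` G(n, m) graphs with the observed node and edge
    counts (or degree-preserving configuration-model graphs when
    ``null_model='configuration'``), re-detecting modules per replicate.
    z = (observed - null mean) / null sd; undefined (NaN) when sd = 0.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if null_model not in {"erdos_renyi", "configuration"}:
        raise ValueError(f"unknown null model {null_model!r}")
    n, m = net.number_of_nodes(), net.number_of_edges()
    if m == 0:
        raise ValueError("observed graph has no edges")
    obs = _properties(net)
    if part is not None:
        obs["modularity_Q"] = getattr(part, "Q", obs["modularity_Q"])
    rng = np.random.default_rng(seed)
    rows = {p: [] for p in COMPARED_PROPERTIES}
    degrees = [d for _, d in net.degree()]
    for _ in range(n_reps):
        if null_model == "erdos_renyi":
            g = er_random_graph(n, m, rng)
        else:
            g = nx.configuration_model(
                degrees, seed=int(rng.integers(2 ** 31)))
            g = nx.Graph(g)
            g.remove_edges_from(nx.selfloop_edges(g))
        props = _properties(g)
        for p in COMPARED_PROPERTIES:
            rows[p].append(props[p])
    table = pd.DataFrame(index=pd.Index(COMPARED_PROPERTIES, name="property"))
    table["observed"] = [obs[p] for p in COMPARED_PROPERTIES]
    table["null_mean"] = [float(np.mean(rows[p])) for p in COMPARED_PROPERTIES]
    table["null_sd"] = [float(np.std(rows[p], ddof=1))
                        for p in COMPARED_PROPERTIES]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (table["observed"] - table["null_mean"]) / table["null_sd"]
    table["z"] = z.where(table["null_sd"] > 0, np.nan)
    return NullComparison(table=table, n_replicates=n_reps, seed=seed,
                          null_model=null_model)
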