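"""Within-module degree z-score (Zi) and participation coefficient (Pi).

The Zi-Pi plane classifies nodes by their topological role relative to the
module structure: Zi measures how hub-like a node is inside its own module,
Pi how evenly its edges spread across modules.  The four-quadrant scheme
with the customary thresholds (Zi = 2.5, Pi = 0.62) labels nodes as
peripherals, connectors, module hubs or network hubs.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .netbuild import ModulePartition

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62

ROLES = ("peripheral", "connector", "module_hub", "network_hub")


def zipi(net: nx.Graph, part, zi_threshold: float = ZI_THRESHOLD,
         pi_threshold: float = PI_THRESHOLD) -> pd.DataFrame:
    """Per-node kappa (within-module degree), Zi, Pi and role.

    Zi standardizes the within-module degree kappa_i against its module's
    mean and population standard deviation (Zi = 0 when the sd is 0, e.g.
    singleton modules — flagged in the ``degenerate_zi`` column).
    Pi = 1 - sum_s (kappa_is / k_i)^2 over modules s; 0 for isolated nodes.
    Roles: below both thresholds -> peripheral; only Pi >= threshold ->
    connector; only Zi >= threshold -> module_hub; both -> network_hub.
    """
    mapping = part.mapping if isinstance(part, ModulePartition) else dict(part)
    missing = [n for n in net.nodes if n not in mapping]
    if missing:
        raise ValueError(f"partition missing nodes: {missing[:10]}")
    nodes = list(net.nodes)
    labels = sorted({mapping[n] for n in nodes})
    lab_idx = {lab: i for i, lab in enumerate(labels)}

    # kappa_is: edges from node i into module s
    kappa_per_mod = np.zeros((len(nodes), len(labels)))
    node_idx = {n: i for i, n in enumerate(nodes)}
    for u, v in net.edges:
        kappa_per_mod[node_idx[u], lab_idx[mapping[v]]] += 1
        kappa_per_mod[node_idx[v], lab_idx[mapping[u]]] += 1
    own = np.array([lab_idx[mapping[n]] for n in nodes])
    kappa = kappa_per_mod[np.arange(len(nodes)), own]
    k_total = kappa_per_mod.sum(axis=1)

    zi = np.zeros(len(nodes))
    degenerate = np.zeros(len(nodes), dtype=bool)
    for lab, s in lab_idx.items():
        members = own == s
        mu = kappa[members].mean()
        sd = kappa[members].std()  # population sd
        if sd == 0:
            degenerate[members] = True
        else:
            zi[members] = (kappa[members] - mu) / sd

    with np.errstate(invalid="ignore", divide="ignore"):
        frac = kappa_per_mod / k_total[:, None]
    pi = 1.0 - np.nansum(frac ** 2, axis=1)
    pi[k_total == 0] = 0.0

    role = np.where(
        zi >= zi_threshold,
        np.where(pi >= pi_threshold, "network_hub", "module_hub"),
        np.where(pi >= pi_threshold, "connector", "peripheral"))

    return pd.DataFrame({
        "module": [mapping[n] for n in nodes],
        "kappa": kappa,
        "zi": zi,
        "pi": pi,
        "role": role,
        "degenerate_zi": degenerate,
    }, index=pd.Index(nodes, name="taxon"))
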