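"""Tables and graph serialization.

The toolkit's canonical in-memory containers are thin wrappers around pandas
objects: an :class:`AbundanceTable` holds a taxon-by-sample matrix (taxa as
rows — the usual orientation of OTU/ASV tables), an edge table is a DataFrame
with columns ``source, target, r, p, sign`` and a node table carries per-node
layout/statistics columns.  Graphs travel as GraphML (readable by Gephi and
Cytoscape) plus plain CSVs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

EDGE_COLUMNS = ["source", "target", "r", "p", "sign"]
NODE_COLUMNS = [
    "taxon", "module", "x", "y", "degree", "zi", "pi", "role", "mean_abundance",
]


class TableValidationError(ValueError):
    """Raised when an input table violates the abundance-table contract."""


@dataclasses.dataclass
class AbundanceTable:
    """Taxon-by-sample non-negative abundance matrix.

    Parameters
    ----------
    values
        DataFrame indexed by taxon ID with sample IDs as columns.  Counts or
        relative abundances; must be finite and non-negative.
    taxonomy
        Optional DataFrame indexed by taxon giving rank labels.
    group
        Optional mapping taxon -> group label (bipartite mode); must cover
        every taxon and contain at least two distinct labels.
    """

    values: pd.DataFrame
    taxonomy: pd.DataFrame | None = None
    group: dict[str, str] | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dups = sorted(set(v.index[v.index.duplicated()].astype(str)))
            raise TableValidationError(f"duplicate taxon IDs: {dups}")
        if v.columns.duplicated().any():
            dups = sorted(set(v.columns[v.columns.duplicated()].astype(str)))
            raise TableValidationError(f"duplicate sample IDs: {dups}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = _first_bad_cell(v, lambda x: not _is_number(x))
            raise TableValidationError(f"non-numeric cell at {bad}")
        if np.isnan(arr).any():
            bad = _first_bad_cell(v, lambda x: pd.isna(x))
            raise TableValidationError(f"missing (NA/empty) cell at {bad}")
        if not np.isfinite(arr).all():
            bad = _first_bad_cell(v, lambda x: not np.isfinite(x))
            raise TableValidationError(f"non-finite cell at {bad}")
        if (arr < 0).any():
            bad = _first_bad_cell(v, lambda x: x < 0)
            raise TableValidationError(f"negative value at {bad}")
        if self.group is not None:
            missing = [t for t in v.index if t not in self.group]
            if missing:
                raise TableValidationError(
                    f"group table missing taxa: {missing[:10]}")
            if len(set(self.group[t] for t in v.index)) < 2:
                raise TableValidationError(
                    "group must contain at least 2 distinct labels")

    @property
    def taxa(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_taxa(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def mean_abundance(self) -> pd.Series:
        return self.values.mean(axis=1)


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def _first_bad_cell(df: pd.DataFrame, pred) -> str:
    for i, row in enumerate(df.index):
        for j, col in enumerate(df.columns):
            if pred(df.iat[i, j]):
                return f"row '{row}', column '{col}'"
    return "<unlocated>"


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def read_abundance(
    path: str | Path,
    orientation: str = "taxa_rows",
    taxonomy: str | Path | None = None,
    group: str | Path | None = None,
) -> AbundanceTable:
    """Read a CSV/TSV abundance table.

    ``orientation`` is ``taxa_rows`` (default) or ``samples_rows``; the
    latter is transposed so taxa index rows internally.  Cells must be
    non-negative numbers; NA/empty cells are rejected rather than imputed.
    """
    path = Path(path)
    if orientation not in {"taxa_rows", "samples_rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if orientation == "samples_rows":
        raw = raw.T
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    tax = None
    if taxonomy is not None:
        tp = Path(taxonomy)
        tax = pd.read_csv(tp, sep=_sep_for(tp), index_col=0)
        tax.index = tax.index.astype(str)
    grp = read_group(group) if group is not None else None
    return AbundanceTable(values=raw, taxonomy=tax, group=grp)


def read_group(path: str | Path) -> dict[str, str]:
    """Read a two-column taxon -> group-label table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return {str(k): str(v) for k, v in df.iloc[:, 0].items()}


def write_abundance(table: AbundanceTable, path: str | Path) -> None:
    path = Path(path)
    table.values.to_csv(path, sep=_sep_for(path))


def make_edge_table(rows) -> pd.DataFrame:
    """Build a validated edge table from (source, target, r, p) rows."""
    df = pd.DataFrame(rows, columns=["source", "target", "r", "p"])
    df["sign"] = np.where(df["r"] > 0, "positive", "negative")
    validate_edge_table(df)
    return df[EDGE_COLUMNS]


def validate_edge_table(df: pd.DataFrame) -> None:
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError(f"edge table missing columns: {missing}")
    if (df["source"] == df["target"]).any():
        raise TableValidationError("edge table contains self-loops")
    pairs = [frozenset((s, t)) for s, t in zip(df["source"], df["target"])]
    if len(pairs) != len(set(pairs)):
        raise TableValidationError("edge table repeats an unordered pair")
    bad = df[(df["r"] > 0) != (df["sign"] == "positive")]
    if len(bad):
        raise TableValidationError("sign column inconsistent with r")


def write_network(
    graph: nx.Graph,
    partition: Mapping[str, str],
    layout=None,
    path_prefix: str | Path = "network",
    extra_node_columns: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write edges.csv, nodes.csv and network.graphml for a network.

    ``partition`` must label every graph node.  ``layout``, when given, is a
    mapping node -> (x, y) over exactly the graph's node set.
    ``path_prefix`` is the output directory (created if needed).
    ``extra_node_columns`` (indexed by taxon) may supply zi/pi/role/
    mean_abundance values; absent columns are written as NA.
    """
    missing = [n for n in graph.nodes if n not in partition]
    if missing:
        raise ValueError(f"partition missing nodes: {missing[:10]}")
    coords = None
    if layout is not None:
        coords = getattr(layout, "coords", layout)
        if set(coords) != set(graph.nodes):
            raise ValueError("layout node set differs from graph node set")

    outdir = Path(path_prefix)
    outdir.mkdir(parents=True, exist_ok=True)

    erows = []
    for u, v, d in graph.edges(data=True):
        r = float(d.get("r", 1.0))
        erows.append((u, v, r, float(d.get("p", np.nan)),
                      "positive" if r > 0 else "negative"))
    edges = pd.DataFrame(erows, columns=EDGE_COLUMNS)
    edges_path = outdir / "edges.csv"
    edges.to_csv(edges_path, index=False)

    nrows = []
    for n in graph.nodes:
        x, y = coords[n] if coords is not None else (np.nan, np.nan)
        row = {
            "taxon": n,
            "module": partition[n],
            "x": x,
            "y": y,
            "degree": graph.degree[n],
            "zi": np.nan,
            "pi": np.nan,
            "role": "",
            "mean_abundance": graph.nodes[n].get("mean_abundance", np.nan),
        }
        if extra_node_columns is not None and n in extra_node_columns.index:
            for c in extra_node_columns.columns:
                if c in row:
                    row[c] = extra_node_columns.loc[n, c]
        nrows.append(row)
    nodes = pd.DataFrame(nrows, columns=NODE_COLUMNS)
    nodes_path = outdir / "nodes.csv"
    nodes.to_csv(nodes_path, index=False)

    g = nx.Graph()
    for n in graph.nodes:
        g.add_node(n, module=str(partition[n]))
    for u, v, d in graph.edges(data=True):
        r = float(d.get("r", 1.0))
        g.add_edge(u, v, r=r, sign="positive" if r > 0 else "negative")
    graphml_path = outdir / "network.graphml"
    nx.write_graphml(g, graphml_path)

    return {"edges": edges_path, "nodes": nodes_path, "graphml": graphml_path}
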