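"""One-command network pipelines and the minimal SVG renderer.

``run_pipeline`` composes every stage — correlation, optional bipartite
restriction, edge filtering, graph construction, module detection, layout,
network/node property tables, Zi-Pi roles, null-model comparison and
serialization — and is a pure composition: invoking the stages by hand with
the seeds recorded in the manifest reproduces its outputs exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .correlation import bipartite_restrict, correlate, filter_edges
from .io_tables import AbundanceTable, write_network
from .netbuild import build_graph, detect_modules, pool_small_modules
from .netstats import net_properties, node_properties
from .nullmodel import compare_to_random
from .layouts import LAYOUTS, LayoutResult, layout
from .zipi import zipi

log = logging.getLogger("micronet")

VERSION = "0.1.0"

MODULE_PALETTE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b",
    "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
]
POSITIVE_COLOR = "#c23b22"
NEGATIVE_COLOR = "#4a6fa5"


@dataclasses.dataclass
class PipelineConfig:
    """Flat pipeline configuration; every field maps to one CLI flag."""

    method: str = "spearman"
    r_min: float = 0.6
    p_max: float = 0.05
    adjust: str = "none"
    min_prevalence: float = 0.0
    algorithm: str = "model_maptree"
    layout_params: dict = dataclasses.field(default_factory=dict)
    min_module_size: int = 1
    isolate_policy: str = "drop"
    bipartite: bool = False
    null_reps: int = 100
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclasses.dataclass
class PipelineResult:
    status: str                  # "ok" or "empty_network"
    outdir: Path
    graph: nx.Graph | None = None
    partition: object = None
    layout: LayoutResult | None = None
    files: dict = dataclasses.field(default_factory=dict)


def _stage_seeds(seed: int) -> dict[str, int]:
    # documented derivation: sub-seeds stay reproducible and below 2^31
    return {"correlation": seed % 2 ** 31,
            "layout": (seed + 1) % 2 ** 31,
            "null": (seed + 2) % 2 ** 31}


def run_pipeline(table: AbundanceTable, config: PipelineConfig,
                 outdir: str | Path) -> PipelineResult:
    """Run the full co-occurrence network pipeline into ``outdir``.

    An empty post-filter network exits gracefully with partial outputs
    (correlation matrices, empty edge table, manifest) retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    files: dict[str, Path] = {}

    cor = correlate(table, method=config.method,
                    min_prevalence=config.min_prevalence,
                    sparcc_permutations=(100 if config.method == "sparcc"
                                         else 0),
                    seed=seeds["correlation"])
    log.info("correlation: %d taxa kept, method=%s", len(cor.taxa),
             cor.method)
    if config.bipartite:
        if table.group is None:
            raise ValueError("bipartite mode requires a group table")
        cor = bipartite_restrict(cor, table.group)
        log.info("bipartite restriction applied (%d groups)",
                 len(set(table.group.values())))
    cor.R.to_csv(outdir / "R.csv")
    cor.P.to_csv(outdir / "P.csv")
    files["R"] = outdir / "R.csv"
    files["P"] = outdir / "P.csv"

    edges = filter_edges(cor, r_min=config.r_min, p_max=config.p_max,
                         adjust=config.adjust)
    log.info("filter: %d edges retained (|r|>=%g, p<=%g, adjust=%s)",
             len(edges), config.r_min, config.p_max, config.adjust)

    manifest = {
        "config": dataclasses.asdict(config),
        "stage_seeds": seeds,
        "versions": _versions(),
        "n_taxa_input": table.n_taxa,
        "n_samples": table.n_samples,
        "n_edges": int(len(edges)),
    }

    if len(edges) == 0:
        edges.to_csv(outdir / "edges.csv", index=False)
        manifest["status"] = "empty_network"
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
        log.warning("empty network after filtering; partial outputs written")
        return PipelineResult(status="empty_network", outdir=outdir,
                              files=files)

    attrs = pd.DataFrame({"mean_abundance": table.mean_abundance()})
    if table.group is not None:
        attrs["group"] = pd.Series(table.group)
    net = build_graph(edges, isolate_policy=config.isolate_policy,
                      nodes=cor.taxa, node_attrs=attrs)
    part = detect_modules(net)
    if config.min_module_size > 1:
        part = pool_small_modules(part, config.min_module_size)
    log.info("modules: %d detected, Q=%.4f", len(part.sizes()), part.Q)

    lay_params = dict(config.layout_params)
    fn = LAYOUTS[config.algorithm]
    import inspect

    if "seed" in inspect.signature(fn).parameters:
        lay_params.setdefault("seed", seeds["layout"])
    lay = layout(net, part, config.algorithm, **lay_params)

    props = net_properties(net, part)
    props.rename_axis("property").to_csv(outdir / "netprops.csv")
    files["netprops"] = outdir / "netprops.csv"

    nodeprops = node_properties(net, part)
    zp = zipi(net, part)
    log.info("zipi: roles %s", zp["role"].value_counts().to_dict())

    comp = compare_to_random(net, part, n_reps=config.null_reps,
                             seed=seeds["null"])
    comp.table.to_csv(outdir / "nullcomp.csv")
    files["nullcomp"] = outdir / "nullcomp.csv"

    extra = zp[["zi", "pi", "role"]].copy()
    extra["mean_abundance"] = table.mean_abundance()
    written = write_network(net, part, layout=lay, path_prefix=outdir,
                            extra_node_columns=extra)
    files.update(written)
    nodeprops.to_csv(outdir / "nodeprops.csv")
    zp.to_csv(outdir / "zipi.csv")
    lay.modules.to_csv(outdir / "modules.csv")
    files["zipi"] = outdir / "zipi.csv"

    svg = render(net, lay, partition=part)
    (outdir / "plot.svg").write_text(svg)
    files["plot"] = outdir / "plot.svg"

    manifest["status"] = "ok"
    manifest["n_modules"] = len(part.sizes())
    manifest["modularity_Q"] = part.Q
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(status="ok", outdir=outdir, graph=net,
                          partition=part, layout=lay, files=files)


def _versions() -> dict[str, str]:
    import networkx
    import numpy
    import pandas
    import scipy

    return {"micronet": VERSION, "numpy": numpy.__version__,
            "scipy": scipy.__version__, "pandas": pandas.__version__,
            "networkx": networkx.__version__}


# ---------------------------------------------------------------------------
# Minimal deterministic SVG renderer
# ---------------------------------------------------------------------------

def render(net: nx.Graph, layout_result: LayoutResult, partition=None,
           style: dict | None = None) -> str:
    """Render a laid-out network as an SVG string.

    Nodes are circles colored by module, edges are segments colored by
    correlation sign; node radius scales with degree (or mean abundance via
    ``style={'size_by': 'abundance'}``).  Coordinates are written verbatim
    as circle centers, so the drawing is an exact record of the layout.
    """
    style = style or {}
    coords = layout_result.coords
    if set(coords) != set(net.nodes):
        raise ValueError("layout node set differs from graph node set")
    if partition is None:
        mods = sorted({""})
        get_mod = lambda n: ""  # noqa: E731
    else:
        mapping = (partition.mapping if hasattr(partition, "mapping")
                   else dict(partition))
        mods = sorted({mapping[n] for n in net.nodes})
        get_mod = lambda n: mapping[n]  # noqa: E731
    color = {m: MODULE_PALETTE[i % len(MODULE_PALETTE)]
             for i, m in enumerate(mods)}

    if coords:
        xs = [p[0] for p in coords.values()]
        ys = [p[1] for p in coords.values()]
        span = max(max(xs) - min(xs), max(ys) - min(ys), 1e-9)
        pad = 0.05 * span + 0.02
        vb = (min(xs) - pad, min(ys) - pad,
              (max(xs) - min(xs)) + 2 * pad, (max(ys) - min(ys)) + 2 * pad)
        base_r = style.get("node_radius", 0.015 * span + 1e-3)
    else:
        vb = (0.0, 0.0, 1.0, 1.0)
        base_r = 0.01

    size_by = style.get("size_by", "degree")
    if size_by == "abundance":
        raw = {n: float(net.nodes[n].get("mean_abundance", 1.0) or 1.0)
               for n in net.nodes}
    else:
        raw = {n: float(net.degree[n]) for n in net.nodes}
    mx = max(raw.values(), default=1.0) or 1.0
    radius = {n: base_r * (0.5 + 1.5 * raw[n] / mx) for n in net.nodes}

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'viewBox="{vb[0]:.6g} {vb[1]:.6g} {vb[2]:.6g} {vb[3]:.6g}">',
        '<g class="edges">',
    ]
    for u, v, d in sorted(net.edges(data=True),
                          key=lambda e: (str(e[0]), str(e[1]))):
        sign = d.get("sign",
                     "positive" if d.get("r", 1.0) > 0 else "negative")
        col = POSITIVE_COLOR if sign == "positive" else NEGATIVE_COLOR
        (x1, y1), (x2, y2) = coords[u], coords[v]
        parts.append(
            f'<line class="edge {sign}" x1="{x1!r}" y1="{y1!r}" '
            f'x2="{x2!r}" y2="{y2!r}" stroke="{col}" '
            f'stroke-width="{0.001 * max(vb[2], vb[3]):.6g}"/>')
    parts.append("</g>")
    parts.append('<g class="nodes">')
    for n in sorted(net.nodes, key=str):
        x, y = coords[n]
        parts.append(
            f'<circle class="node" data-taxon="{n}" '
            f'data-module="{get_mod(n)}" cx="{x!r}" cy="{y!r}" '
            f'r="{radius[n]:.6g}" fill="{color[get_mod(n)]}"/>')
    parts.append("</g>")
    parts.append("</svg>")
    return "\n".join(parts)
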