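"""Module-aware network layout algorithms.

Ten layout algorithms place the nodes of a modular co-occurrence network so
that modules read as visual units.  Most arrange each module's nodes on (or
inside) its own circle and then place the module circles — on the vertices
of a regular polygon, in rows, at random non-overlapping positions, at
user-given coordinates, or by progressive circle packing.  Two exceptions
use classical whole-graph schemes: a single shared circle with contiguous
per-module arcs, and a Fruchterman-Reingold force-directed embedding.

All layouts are pure functions of (graph, partition, parameters, seed) and
return a :class:`LayoutResult` with per-node coordinates and per-module
circle geometry.

Conventions
-----------
* Modules are processed in size-rank order (``module_1`` is the largest).
* Within a ring, nodes are ordered by degree descending, ties broken by
  taxon ID, so hubs occupy the same angular position across modules.
* On-ring layouts size rings by circumference (radius proportional to node
  count); fill-the-disc layouts size discs by area (radius proportional to
  the square root of node count).
* ``gap`` (minimum clearance between module circles) defaults to one tenth
  of the largest module radius, so all separations scale with the layout.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .netbuild import ModulePartition

GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))
PACK_TOL = 1e-9  # circle-overlap tolerance in progressive packing


@dataclasses.dataclass
class CircleSpec:
    """A circle: center and positive radius."""

    cx: float
    cy: float
    radius: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.radius) and self.radius > 0):
            raise ValueError(f"radius must be finite and > 0, got {self.radius}")


@dataclasses.dataclass
class LayoutResult:
    """Per-node coordinates plus per-module circle geometry.

    ``modules`` is a DataFrame indexed by module label with columns
    ``cx, cy, radius``; radius is NaN for layouts without module discs
    (the shared-circle and force-directed algorithms).
    """

    coords: dict[str, tuple[float, float]]
    modules: pd.DataFrame
    algorithm: str
    seed: int | None = None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(n, x, y) for n, (x, y) in self.coords.items()],
            columns=["taxon", "x", "y"]).set_index("taxon")


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def node_order(net: nx.Graph, nodes: Sequence[str]) -> list[str]:
    """Degree descending, ties by taxon ID."""
    return sorted(nodes, key=lambda n: (-net.degree[n], str(n)))


def ring_positions(n: int, center: tuple[float, float] = (0.0, 0.0),
                   radius: float = 1.0,
                   start_angle: float = 0.0) -> np.ndarray:
    """n points evenly spaced counterclockwise on a circle.

    Point k sits at angle ``start_angle + 2*pi*k/n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    k = np.arange(n)
    ang = start_angle + 2.0 * np.pi * k / n
    return np.column_stack([center[0] + radius * np.cos(ang),
                            center[1] + radius * np.sin(ang)])


def polygon_centers(m: int, radii: Sequence[float],
                    gap: float = 0.0) -> np.ndarray:
    """Centers for m module circles on a regular m-gon.

    One module sits at the origin.  Otherwise vertex k lies at angle
    ``pi/2 + 2*pi*k/m`` (module_1 at top, counterclockwise) on a circumradius
    R = (2*max(radii) + gap) / (2*sin(pi/m)), which makes adjacent — hence
    all — circles clear each other by at least ``gap``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if m == 1:
        return np.zeros((1, 2))
    R = (2.0 * max(radii) + gap) / (2.0 * math.sin(math.pi / m))
    k = np.arange(m)
    ang = math.pi / 2.0 + 2.0 * np.pi * k / m
    return np.column_stack([R * np.cos(ang), R * np.sin(ang)])


def _module_groups(net: nx.Graph, part) -> dict[str, list[str]]:
    """Module label -> degree-ordered node list, modules in size-rank order."""
    mapping = part.mapping if isinstance(part, ModulePartition) else dict(part)
    groups: dict[str, list[str]] = {}
    for n in net.nodes:
        groups.setdefault(mapping[n], []).append(n)
    ranked = sorted(groups, key=lambda lab: (-len(groups[lab]),
                                             min(str(x) for x in groups[lab])))
    return {lab: node_order(net, groups[lab]) for lab in ranked}


def _default_gap(gap: float | None, radii: Sequence[float]) -> float:
    return 0.1 * max(radii) if gap is None else gap


def _result(net, groups, centers, radii, coords, algorithm,
            seed=None) -> LayoutResult:
    mods = pd.DataFrame(
        {"cx": [c[0] for c in centers], "cy": [c[1] for c in centers],
         "radius": list(radii)},
        index=pd.Index(list(groups), name="module"))
    return LayoutResult(coords=coords, modules=mods, algorithm=algorithm,
                        seed=seed)


def _rings_at(groups: Mapping[str, list[str]], centers, radii) -> dict:
    coords = {}
    for (lab, members), center, radius in zip(groups.items(), centers, radii):
        pts = ring_positions(len(members), tuple(center), radius)
        for node, (x, y) in zip(members, pts):
            coords[node] = (float(x), float(y))
    return coords


def _random_disc_centers(m: int, radii: Sequence[float], gap: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample m centers with pairwise clearance >= gap.

    Proposals are uniform in a square of side 2*sqrt(m)*(2*max_r + gap);
    after 1000 consecutive rejections the square side doubles, so placement
    always terminates.
    """
    rmax = max(radii)
    side = 2.0 * math.sqrt(m) * (2.0 * rmax + gap)
    centers: list[np.ndarray] = []
    fails = 0
    while len(centers) < m:
        p = rng.uniform(0.0, side, size=2)
        ri = radii[len(centers)]
        ok = all(np.hypot(*(p - q)) >= ri + radii[j] + gap
                 for j, q in enumerate(centers))
        if ok:
            centers.append(p)
            fails = 0
        else:
            fails += 1
            if fails >= 1000:
                side *= 2.0
                fails = 0
    return np.array(centers)


# ---------------------------------------------------------------------------
# Ring-of-modules layouts
# ---------------------------------------------------------------------------

def layout_polygon_cluster(net: nx.Graph, part, ring_radius: float = 1.0,
                           gap: float | None = None) -> LayoutResult:
    """PolygonClusterG: equal-radius module rings on regular-polygon vertices."""
    groups = _module_groups(net, part)
    radii = [ring_radius] * len(groups)
    gap = _default_gap(gap, radii)
    centers = polygon_centers(len(groups), radii, gap)
    coords = _rings_at(groups, centers, radii)
    return _result(net, groups, centers, radii, coords, "PolygonClusterG")


def layout_polygon_rr_cluster(net: nx.Graph, part, scale: float = 1.0,
                              gap: float | None = None) -> LayoutResult:
    """PolygonRrClusterG: ring radius grows with module size.

    Module k's ring radius is ``scale * n_k / (2*pi)``, so the arc length
    between adjacent nodes equals ``scale`` in every ring.
    """
    groups = _module_groups(net, part)
    radii = [scale * len(m) / (2.0 * math.pi) for m in groups.values()]
    gap = _default_gap(gap, radii)
    centers = polygon_centers(len(groups), radii, gap)
    coords = _rings_at(groups, centers, radii)
    return _result(net, groups, centers, radii, coords, "PolygonRrClusterG")


def layout_random_cluster(net: nx.Graph, part, ring_radius: float = 1.0,
                          gap: float | None = None,
                          seed: int | None = None) -> LayoutResult:
    """randomClusterG: equal-radius module rings at random disjoint positions."""
    groups = _module_groups(net, part)
    radii = [ring_radius] * len(groups)
    gap = _default_gap(gap, radii)
    rng = np.random.default_rng(seed)
    centers = _random_disc_centers(len(groups), radii, gap, rng)
    coords = _rings_at(groups, centers, radii)
    return _result(net, groups, centers, radii, coords, "randomClusterG", seed)


def layout_artif_cluster(net: nx.Graph, part,
                         centers: Mapping[str, tuple[float, float]],
                         ring_radius: float = 1.0) -> LayoutResult:
    """ArtifCluster: equal-radius module rings at user-given centers.

    Overlapping centers are honored (user intent) with a warning.
    """
    import warnings as _warnings

    groups = _module_groups(net, part)
    missing = [lab for lab in groups if lab not in centers]
    if missing:
        raise ValueError(f"centers missing for modules: {missing}")
    cts = [np.asarray(centers[lab], dtype=float) for lab in groups]
    radii = [ring_radius] * len(groups)
    for i in range(len(cts)):
        for j in range(i + 1, len(cts)):
            if np.hypot(*(cts[i] - cts[j])) < 2 * ring_radius:
                _warnings.warn("user-supplied module circles overlap",
                               stacklevel=2)
    coords = _rings_at(groups, cts, radii)
    return _result(net, groups, cts, radii, coords, "ArtifCluster")


def layout_rand_sna_cluster(net: nx.Graph, part,
                            sublayout: str = "fruchterman_reingold",
                            ring_radius: float = 1.0,
                            gap: float | None = None,
                            seed: int | None = None) -> LayoutResult:
    """randSNEClusterG: classical per-module sublayouts in random discs.

    Each module's induced subgraph is laid out by ``sublayout``
    (``fruchterman_reingold`` or ``circle``), centered and rescaled so the
    farthest node sits at ``ring_radius``; the module discs are then placed
    by the same random rejection scheme as randomClusterG.
    """
    if sublayout not in {"fruchterman_reingold", "circle"}:
        raise ValueError(f"unknown sublayout {sublayout!r}")
    groups = _module_groups(net, part)
    radii = [ring_radius] * len(groups)
    gap = _default_gap(gap, radii)
    rng = np.random.default_rng(seed)
    centers = _random_disc_centers(len(groups), radii, gap, rng)
    coords = {}
    for i, ((lab, members), center) in enumerate(zip(groups.items(), centers)):
        if len(members) == 1:
            coords[members[0]] = (float(center[0]), float(center[1]))
            continue
        if sublayout == "circle":
            pts = ring_positions(len(members), (0.0, 0.0), ring_radius)
        else:
            sub = net.subgraph(members)
            sub_seed = None if seed is None else (seed * 1000 + i) % (2 ** 31)
            res = layout_model_igraph(sub, seed=sub_seed)
            pts = np.array([res.coords[n] for n in members])
            pts -= pts.mean(axis=0)
            norm = np.max(np.hypot(pts[:, 0], pts[:, 1]))
            if norm > 0:
                pts *= ring_radius / norm
        for node, (x, y) in zip(members, pts + center):
            coords[node] = (float(x), float(y))
    return _result(net, groups, centers, radii, coords, "randSNEClusterG",
                   seed)


def layout_polygon_mod_square(net: nx.Graph, part, scale: float = 1.0,
                              gap: float | None = None,
                              row_len: int | None = None) -> LayoutResult:
    """PolygonModsquareG: size-scaled rings arranged left-to-right in rows.

    Rings (radius as in PolygonRrClusterG) are placed in size-rank order in
    rows of ``row_len`` (default ceil(sqrt(m))).  Consecutive centers in a
    row are separated horizontally by the two radii plus ``gap``; rows are
    separated vertically by the adjacent rows' largest radii plus ``gap``.
    """
    groups = _module_groups(net, part)
    m = len(groups)
    radii = [scale * len(mem) / (2.0 * math.pi) for mem in groups.values()]
    gap = _default_gap(gap, radii)
    if row_len is None:
        row_len = math.ceil(math.sqrt(m))
    rows = [list(range(i, min(i + row_len, m)))
            for i in range(0, m, row_len)]
    centers = np.zeros((m, 2))
    y = 0.0
    for ri, row in enumerate(rows):
        if ri > 0:
            prev = rows[ri - 1]
            y -= max(radii[k] for k in prev) + max(radii[k] for k in row) + gap
        x = 0.0
        for ci, k in enumerate(row):
            if ci > 0:
                x += radii[row[ci - 1]] + radii[k] + gap
            centers[k] = (x, y)
    coords = _rings_at(groups, centers, radii)
    return _result(net, groups, centers, radii, coords, "PolygonModsquareG")


def layout_poly_rdm_notd_cir(net: nx.Graph, part, scale: float = 1.0,
                             gap: float | None = None,
                             seed: int | None = None) -> LayoutResult:
    """PolyRdmNotdCirG: nodes uniform inside size-scaled discs on a polygon.

    Disc radius is ``scale * sqrt(n_k)`` (constant expected node density);
    discs sit on regular-polygon vertices; nodes are i.i.d. uniform in
    their disc (radius r*sqrt(u), angle 2*pi*v).
    """
    groups = _module_groups(net, part)
    radii = [scale * math.sqrt(len(m)) for m in groups.values()]
    gap = _default_gap(gap, radii)
    centers = polygon_centers(len(groups), radii, gap)
    rng = np.random.default_rng(seed)
    coords = {}
    for (lab, members), center, radius in zip(groups.items(), centers, radii):
        u = rng.random(len(members))
        v = rng.random(len(members))
        rho = radius * np.sqrt(u)
        ang = 2.0 * np.pi * v
        for node, r_, a_ in zip(members, rho, ang):
            coords[node] = (float(center[0] + r_ * math.cos(a_)),
                            float(center[1] + r_ * math.sin(a_)))
    return _result(net, groups, centers, radii, coords, "PolyRdmNotdCirG",
                   seed)


# ---------------------------------------------------------------------------
# Shared-circle layout
# ---------------------------------------------------------------------------

def layout_model_gephi2(net: nx.Graph, part, circle_radius: float = 1.0,
                        gap_angle: float = 0.1,
                        start_angle: float = 0.0) -> LayoutResult:
    """model_Gephi.2: one shared circle, modules as contiguous arcs.

    Modules occupy arcs in size-rank order; arc length is proportional to
    module size within the angle left after ``gap_angle`` radians between
    consecutive modules.  Node k of a module sits at fraction k/n of its
    arc, degree-descending order.
    """
    groups = _module_groups(net, part)
    m = len(groups)
    total_nodes = sum(len(g) for g in groups.values())
    avail = 2.0 * np.pi - m * gap_angle
    if avail <= 0:
        raise ValueError("gap_angle too large for the number of modules")
    coords = {}
    centroids = []
    ang = start_angle
    for lab, members in groups.items():
        span = avail * len(members) / total_nodes
        for k, node in enumerate(members):
            a = ang + span * k / len(members)
            coords[node] = (float(circle_radius * math.cos(a)),
                            float(circle_radius * math.sin(a)))
        mid = ang + span / 2.0
        centroids.append((circle_radius * math.cos(mid),
                          circle_radius * math.sin(mid)))
        ang += span + gap_angle
    mods = pd.DataFrame(
        {"cx": [c[0] for c in centroids], "cy": [c[1] for c in centroids],
         "radius": np.nan},
        index=pd.Index(list(groups), name="module"))
    return LayoutResult(coords=coords, modules=mods,
                        algorithm="model_Gephi.2")


# ---------------------------------------------------------------------------
# Force-directed layout
# ---------------------------------------------------------------------------

def layout_model_igraph(net: nx.Graph, part=None, iterations: int = 200,
                        seed: int | None = None,
                        area: float | None = None) -> LayoutResult:
    """model_igraph: Fruchterman-Reingold force-directed embedding.

    Standard FR with ideal edge length k = sqrt(area/n): repulsive force
    k^2/d between every pair, attractive force d^2/k along edges;
    per-iteration displacement is capped by a temperature cooled linearly
    from 0.1*sqrt(area) to zero.  Initial positions are uniform in the
    area square.  The partition is accepted (for dispatch uniformity) but
    plays no role; module grouping is an emergent property.
    """
    nodes = list(net.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("cannot lay out an empty graph")
    if area is None:
        area = float(n)
    side = math.sqrt(area)
    k = math.sqrt(area / n)
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, side, size=(n, 2))
    idx = {v: i for i, v in enumerate(nodes)}
    edges = np.array([(idx[u], idx[v]) for u, v in net.edges], dtype=int)
    t0 = 0.1 * side
    for it in range(iterations):
        t = t0 * (1.0 - it / iterations)
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.hypot(delta[..., 0], delta[..., 1])
        np.fill_diagonal(dist, 1.0)
        dist = np.maximum(dist, 1e-9)
        # repulsion k^2/d between all pairs
        disp = (delta / dist[..., None] * (k * k / dist)[..., None]).sum(axis=1)
        if len(edges):
            ev = pos[edges[:, 0]] - pos[edges[:, 1]]
            ed = np.maximum(np.hypot(ev[:, 0], ev[:, 1]), 1e-9)
            f = (ed ** 2 / k) / ed  # attraction d^2/k, as unit-vector factor
            pull = ev * f[:, None]
            np.add.at(disp, edges[:, 0], -pull)
            np.add.at(disp, edges[:, 1], pull)
        length = np.maximum(np.hypot(disp[:, 0], disp[:, 1]), 1e-12)
        pos += disp / length[:, None] * np.minimum(length, t)[:, None]
    coords = {v: (float(pos[i, 0]), float(pos[i, 1]))
              for v, i in idx.items()}
    if part is not None:
        groups = _module_groups(net, part)
        cent = [np.mean([coords[v] for v in mem], axis=0)
                for mem in groups.values()]
        mods = pd.DataFrame(
            {"cx": [c[0] for c in cent], "cy": [c[1] for c in cent],
             "radius": np.nan},
            index=pd.Index(list(groups), name="module"))
    else:
        mods = pd.DataFrame(columns=["cx", "cy", "radius"],
                            index=pd.Index([], name="module"))
    return LayoutResult(coords=coords, modules=mods,
                        algorithm="model_igraph", seed=seed)


# ---------------------------------------------------------------------------
# Progressive circle packing
# ---------------------------------------------------------------------------

def _tangency_candidates(p1, r1, p2, r2, r):
    """Centers of a radius-r circle externally tangent to two placed circles."""
    R1, R2 = r1 + r, r2 + r
    d = math.hypot(p2[0] - p1[0], p2[1] - p1[1])
    if d == 0 or d > R1 + R2 or d < abs(R1 - R2):
        return []
    a = (d * d + R1 * R1 - R2 * R2) / (2.0 * d)
    h2 = R1 * R1 - a * a
    if h2 < 0:
        return []
    h = math.sqrt(max(h2, 0.0))
    ux, uy = (p2[0] - p1[0]) / d, (p2[1] - p1[1]) / d
    bx, by = p1[0] + a * ux, p1[1] + a * uy
    return [(bx - h * uy, by + h * ux), (bx + h * uy, by - h * ux)]


def pack_circles_progressive(radii: Sequence[float]) -> list[CircleSpec]:
    """Pack circles one by one, each as close to the origin as possible.

    The first circle sits at the origin, the second tangent to it on the
    +x axis; each later circle is placed externally tangent to a pair of
    already-placed circles, choosing among all non-overlapping tangency
    candidates the center nearest the origin (ties by smaller polar angle
    in [0, 2*pi)).
    """
    placed: list[CircleSpec] = []
    for r in radii:
        if r <= 0:
            raise ValueError(f"radii must be > 0, got {r}")
        if not placed:
            placed.append(CircleSpec(0.0, 0.0, r))
            continue
        if len(placed) == 1:
            placed.append(CircleSpec(placed[0].cx + placed[0].radius + r,
                                     placed[0].cy, r))
            continue
        best = None
        for i in range(len(placed)):
            for j in range(i + 1, len(placed)):
                a, b = placed[i], placed[j]
                for cand in _tangency_candidates(
                        (a.cx, a.cy), a.radius, (b.cx, b.cy), b.radius, r):
                    ok = all(math.hypot(cand[0] - c.cx, cand[1] - c.cy)
                             >= c.radius + r - PACK_TOL for c in placed)
                    if not ok:
                        continue
                    d0 = math.hypot(*cand)
                    ang = math.atan2(cand[1], cand[0]) % (2.0 * math.pi)
                    key = (round(d0, 9), round(ang, 9))
                    if best is None or key < best[0]:
                        best = (key, cand)
        if best is None:  # unreachable for sane inputs; stay safe
            far = max(placed, key=lambda c: math.hypot(c.cx, c.cy))
            d = math.hypot(far.cx, far.cy) or 1.0
            cand = (far.cx * (1 + (far.radius + r) / d),
                    far.cy * (1 + (far.radius + r) / d))
            best = (None, cand)
        placed.append(CircleSpec(best[1][0], best[1][1], r))
    return placed


def layout_model_maptree(net: nx.Graph, part, scale: float = 1.0,
                         pad: float = 0.0) -> LayoutResult:
    """model_maptree: progressively packed module circles, phyllotaxis fill.

    Module circles (radius ``scale*sqrt(n_k) + pad``) are packed densely
    around the origin in decreasing-size order; inside each circle, nodes
    follow a sunflower spiral — node j at radius
    ``0.9 * r * sqrt((j+0.5)/n)`` and angle ``j * golden_angle`` — which
    keeps every node strictly inside its circle at near-uniform density.
    """
    groups = _module_groups(net, part)
    radii = [scale * math.sqrt(len(m)) + pad for m in groups.values()]
    packed = pack_circles_progressive(radii)
    coords = {}
    for (lab, members), spec in zip(groups.items(), packed):
        nk = len(members)
        for j, node in enumerate(members):
            rho = spec.radius * math.sqrt((j + 0.5) / nk) * 0.9
            ang = j * GOLDEN_ANGLE
            coords[node] = (float(spec.cx + rho * math.cos(ang)),
                            float(spec.cy + rho * math.sin(ang)))
    centers = [(c.cx, c.cy) for c in packed]
    return _result(net, groups, centers, [c.radius for c in packed], coords,
                   "model_maptree")


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

LAYOUTS: dict[str, Callable] = {
    "randomClusterG": layout_random_cluster,
    "PolygonClusterG": layout_polygon_cluster,
    "PolygonRrClusterG": layout_polygon_rr_cluster,
    "ArtifCluster": layout_artif_cluster,
    "randSNEClusterG": layout_rand_sna_cluster,
    "PolygonModsquareG": layout_polygon_mod_square,
    "PolyRdmNotdCirG": layout_poly_rdm_notd_cir,
    "model_Gephi.2": layout_model_gephi2,
    "model_igraph": layout_model_igraph,
    "model_maptree": layout_model_maptree,
}


def layout(net: nx.Graph, part, algorithm: str, **params) -> LayoutResult:
    """Run one of the ten registered layout algorithms by name."""
    if algorithm not in LAYOUTS:
        raise ValueError(
            f"unknown layout {algorithm!r}; valid: {sorted(LAYOUTS)}")
    if algorithm == "ArtifCluster" and "centers" not in params:
        groups = _module_groups(net, part)
        r = params.get("ring_radius", 1.0)
        cts = polygon_centers(len(groups), [r] * len(groups), 0.1 * r)
        params["centers"] = {lab: tuple(c) for lab, c in zip(groups, cts)}
    return LAYOUTS[algorithm](net, part, **params)
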