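"""Geometry laws of the ten layout algorithms.

Brute-force checks: ring-distance law, polygon separation, disc
disjointness, packing tangency, scale equivariance and determinism.
"""

import inspect
import itertools
import math

import networkx as nx
import numpy as np
import pytest

from micronet import (
    LAYOUTS,
    ModulePartition,
    layout,
    pack_circles_progressive,
    polygon_centers,
    ring_positions,
)
from micronet.layouts import (
    layout_artif_cluster,
    layout_model_gephi2,
    layout_model_igraph,
    layout_model_maptree,
    layout_poly_rdm_notd_cir,
    layout_polygon_cluster,
    layout_polygon_mod_square,
    layout_polygon_rr_cluster,
    layout_rand_sna_cluster,
    layout_random_cluster,
)

DISC_LAYOUTS = [
    "randomClusterG", "PolygonClusterG", "PolygonRrClusterG", "ArtifCluster",
    "randSNEClusterG", "PolygonModsquareG", "PolyRdmNotdCirG",
    "model_maptree",
]


def _kwargs_for(name, seed=11):
    fn = LAYOUTS[name]
    kw = {}
    if "seed" in inspect.signature(fn).parameters:
        kw["seed"] = seed
    return kw


def _pairwise_disc_separation(res):
    mods = res.modules.dropna(subset=["radius"])
    worst = np.inf
    for (la, a), (lb, b) in itertools.combinations(mods.iterrows(), 2):
        d = math.hypot(a.cx - b.cx, a.cy - b.cy)
        worst = min(worst, d - a.radius - b.radius)
    return worst


@pytest.fixture
def modular_net():
    """12/7/3-node modules with dense intra- and sparse inter-edges."""
    rng = np.random.default_rng(4)
    g = nx.Graph()
    blocks = {"module_1": [f"a{i:02d}" for i in range(12)],
              "module_2": [f"b{i:02d}" for i in range(7)],
              "module_3": [f"c{i:02d}" for i in range(3)]}
    mapping = {}
    for lab, mem in blocks.items():
        for n in mem:
            mapping[n] = lab
        for u, v in itertools.combinations(mem, 2):
            if rng.random() < 0.7:
                g.add_edge(u, v, r=0.8)
    g.add_nodes_from(mapping)
    g.add_edge("a00", "b00", r=-0.7)
    g.add_edge("b00", "c00", r=0.7)
    return g, ModulePartition(mapping=mapping, Q=0.5)


class TestRingPositions:
    def test_single_node_at_start_angle(self):
        pts = ring_positions(1, (2.0, 3.0), 1.5, start_angle=0.3)
        np.testing.assert_allclose(
            pts[0], [2 + 1.5 * np.cos(0.3), 3 + 1.5 * np.sin(0.3)])

    def test_quadrant_symmetry(self):
        pts = ring_positions(4, (0, 0), 1.0, 0.0)
        np.testing.assert_allclose(
            pts, [(1, 0), (0, 1), (-1, 0), (0, -1)], atol=1e-12)

    @pytest.mark.parametrize("n", [1, 2, 5, 17])
    def test_all_points_on_circle(self, n):
        pts = ring_positions(n, (1.0, -2.0), 3.0)
        d = np.hypot(pts[:, 0] - 1.0, pts[:, 1] + 2.0)
        np.testing.assert_allclose(d, 3.0, atol=1e-12)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            ring_positions(3, radius=0.0)


class TestPolygonCenters:
    def test_single_module_at_origin(self):
        np.testing.assert_allclose(polygon_centers(1, [1.0]), [[0, 0]])

    def test_two_equal_discs_diametric(self):
        c = polygon_centers(2, [1.0, 1.0], gap=0.5)
        assert math.hypot(*(c[0] - c[1])) == pytest.approx(2.5)

    def test_square_angle_convention(self):
        c = polygon_centers(4, [1.0] * 4, gap=0.1)
        ang = np.degrees(np.arctan2(c[:, 1], c[:, 0])) % 360
        diff = (ang - np.array([90, 180, 270, 0]) + 180) % 360 - 180
        np.testing.assert_allclose(diff, 0.0, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_min_separation_at_least_gap(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 9))
        radii = rng.uniform(0.2, 3.0, m)
        gap = float(rng.uniform(0.01, 1.0))
        c = polygon_centers(m, radii, gap)
        for i, j in itertools.combinations(range(m), 2):
            d = math.hypot(*(c[i] - c[j]))
            assert d - radii[i] - radii[j] >= gap - 1e-9


class TestRingLayouts:
    def test_single_module_one_origin_ring(self):
        g = nx.complete_graph(6)
        part = ModulePartition({n: "module_1" for n in g.nodes}, 0.0)
        res = layout_polygon_cluster(g, part, ring_radius=2.0)
        for x, y in res.coords.values():
            assert math.hypot(x, y) == pytest.approx(2.0)

    def test_ring_distance_law(self, modular_net):
        g, part = modular_net
        for fn in (layout_polygon_cluster, layout_polygon_rr_cluster):
            res = fn(g, part)
            mods = res.modules
            for n, (x, y) in res.coords.items():
                row = mods.loc[part[n]]
                d = math.hypot(x - row.cx, y - row.cy)
                assert d == pytest.approx(row.radius, abs=1e-9)

    def test_rr_radius_proportional_to_size(self):
        g = nx.Graph()
        mapping = {}
        for i in range(10):
            mapping[f"a{i}"] = "module_1"
        for i in range(20):
            mapping[f"b{i}"] = "module_2"
        g.add_nodes_from(mapping)
        part = ModulePartition(mapping, 0.0)
        res = layout_polygon_rr_cluster(g, part, scale=1.0)
        r = res.modules["radius"]
        assert r["module_2"] / r["module_1"] == pytest.approx(2.0)

    def test_rr_arc_length_equals_scale(self, modular_net):
        g, part = modular_net
        res = layout_polygon_rr_cluster(g, part, scale=0.7)
        for lab, members in part.modules().items():
            members = [n for n in members if n in g]
            r = res.modules.loc[lab, "radius"]
            assert 2 * math.pi * r / len(members) == pytest.approx(0.7,
                                                                   abs=1e-9)

    def test_equal_sizes_reduce_to_polygon_cluster(self):
        g = nx.Graph()
        mapping = {}
        for mod in "AB":
            for i in range(8):
                mapping[f"{mod}{i}"] = f"module_{'AB'.index(mod) + 1}"
        g.add_nodes_from(mapping)
        part = ModulePartition(mapping, 0.0)
        r = 1.0 * 8 / (2 * math.pi)
        res_rr = layout_polygon_rr_cluster(g, part, scale=1.0, gap=0.3)
        res_eq = layout_polygon_cluster(g, part, ring_radius=r, gap=0.3)
        for n in g.nodes:
            np.testing.assert_allclose(res_rr.coords[n], res_eq.coords[n],
                                       atol=1e-9)

    def test_random_cluster_respects_separation(self, modular_net):
        g, part = modular_net
        for seed in range(5):
            res = layout_random_cluster(g, part, ring_radius=1.0, gap=0.4,
                                        seed=seed)
            assert _pairwise_disc_separation(res) >= 0.4 - 1e-9

    def test_artif_composition_equals_polygon(self, modular_net):
        g, part = modular_net
        res_p = layout_polygon_cluster(g, part, ring_radius=1.0, gap=0.1)
        centers = {lab: (row.cx, row.cy)
                   for lab, row in res_p.modules.iterrows()}
        res_a = layout_artif_cluster(g, part, centers, ring_radius=1.0)
        for n in g.nodes:
            np.testing.assert_allclose(res_a.coords[n], res_p.coords[n],
                                       atol=1e-12)

    def test_artif_missing_module_listed(self, modular_net):
        g, part = modular_net
        with pytest.raises(ValueError, match="module_3"):
            layout_artif_cluster(g, part, {"module_1": (0, 0),
                                           "module_2": (5, 0)})

    def test_artif_overlap_warns_but_honors(self, modular_net):
        g, part = modular_net
        centers = {lab: (0.0, 0.0) for lab in part.modules()}
        with pytest.warns(UserWarning, match="overlap"):
            res = layout_artif_cluster(g, part, centers, ring_radius=1.0)
        assert len(res.coords) == g.number_of_nodes()

    def test_artif_centroid_at_given_center(self):
        g = nx.Graph()
        mapping = {}
        for i in range(6):
            mapping[f"a{i}"] = "module_1"
            mapping[f"b{i}"] = "module_2"
        g.add_nodes_from(mapping)
        part = ModulePartition(mapping, 0.0)
        res = layout_artif_cluster(
            g, part, {"module_1": (0.0, 0.0), "module_2": (10.0, 0.0)})
        a = np.mean([res.coords[f"a{i}"] for i in range(6)], axis=0)
        b = np.mean([res.coords[f"b{i}"] for i in range(6)], axis=0)
        np.testing.assert_allclose(a, (0, 0), atol=1e-9)
        np.testing.assert_allclose(b, (10, 0), atol=1e-9)


class TestRandSnaCluster:
    def test_circle_sublayout_reduces_to_rings(self, modular_net):
        g, part = modular_net
        res = layout_rand_sna_cluster(g, part, sublayout="circle",
                                      ring_radius=1.0, seed=3)
        mods = res.modules
        for n, (x, y) in res.coords.items():
            row = mods.loc[part[n]]
            d = math.hypot(x - row.cx, y - row.cy)
            assert d == pytest.approx(1.0, abs=1e-9)

    def test_singleton_module_at_disc_center(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("solo")
        part = ModulePartition({"a": "module_1", "b": "module_1",
                                "solo": "module_2"}, 0.0)
        res = layout_rand_sna_cluster(g, part, seed=1)
        row = res.modules.loc["module_2"]
        np.testing.assert_allclose(res.coords["solo"], (row.cx, row.cy))

    def test_discs_pairwise_separated(self, modular_net):
        g, part = modular_net
        res = layout_rand_sna_cluster(g, part, ring_radius=1.0, gap=0.5,
                                      seed=7)
        assert _pairwise_disc_separation(res) >= 0.5 - 1e-9

    def test_nodes_stay_within_disc(self, modular_net):
        g, part = modular_net
        res = layout_rand_sna_cluster(g, part, ring_radius=1.0, seed=7)
        for n, (x, y) in res.coords.items():
            row = res.modules.loc[part[n]]
            assert math.hypot(x - row.cx, y - row.cy) <= 1.0 + 1e-9


class TestModSquare:
    def test_single_module_origin(self):
        g = nx.complete_graph(5)
        part = ModulePartition({n: "module_1" for n in g.nodes}, 0.0)
        res = layout_polygon_mod_square(g, part)
        np.testing.assert_allclose(
            res.modules[["cx", "cy"]].to_numpy(), [[0, 0]], atol=1e-12)

    def test_four_equal_modules_form_rectangle(self):
        g = nx.Graph()
        mapping = {}
        for k in range(4):
            for i in range(6):
                mapping[f"m{k}n{i}"] = f"module_{k + 1}"
        g.add_nodes_from(mapping)
        part = ModulePartition(mapping, 0.0)
        res = layout_polygon_mod_square(g, part, row_len=2)
        c = res.modules[["cx", "cy"]].to_numpy()
        assert len({round(x, 9) for x in c[:, 0]}) == 2
        assert len({round(y, 9) for y in c[:, 1]}) == 2

    @pytest.mark.parametrize("seed", range(4))
    def test_no_disc_overlap(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.Graph()
        mapping = {}
        for k in range(int(rng.integers(2, 7))):
            for i in range(int(rng.integers(1, 15))):
                mapping[f"m{k}n{i}"] = f"module_{k + 1}"
        g.add_nodes_from(mapping)
        part = ModulePartition(mapping, 0.0)
        res = layout_polygon_mod_square(g, part)
        assert _pairwise_disc_separation(res) >= -1e-9


class TestPolyRdmNotdCir:
    def test_nodes_inside_own_disc(self, modular_net):
        g, part = modular_net
        res = layout_poly_rdm_notd_cir(g, part, seed=5)
        for n, (x, y) in res.coords.items():
            row = res.modules.loc[part[n]]
            assert math.hypot(x - row.cx, y - row.cy) <= row.radius + 1e-12

    def test_radius_sqrt_proportionality(self):
        g = nx.Graph()
        mapping = {f"a{i}": "module_1" for i in range(36)}
        mapping.update({f"b{i}": "module_2" for i in range(9)})
        g.add_nodes_from(mapping)
        part = ModulePartition(mapping, 0.0)
        res = layout_poly_rdm_notd_cir(g, part, scale=1.0, seed=0)
        r = res.modules["radius"]
        assert r["module_1"] / r["module_2"] == pytest.approx(2.0)

    def test_uniform_disc_mean_radius_two_thirds(self):
        # E(rho) = 2/3 for uniform sampling in a unit disc
        n = 10_000
        g = nx.Graph()
        mapping = {f"n{i:05d}": "module_1" for i in range(n)}
        g.add_nodes_from(mapping)
        part = ModulePartition(mapping, 0.0)
        res = layout_poly_rdm_notd_cir(g, part, scale=1.0 / math.sqrt(n),
                                       seed=123)
        d = [math.hypot(x, y) for x, y in res.coords.values()]
        assert np.mean(d) == pytest.approx(2.0 / 3.0, abs=0.02)


class TestGephi2:
    def test_all_on_shared_circle(self, modular_net):
        g, part = modular_net
        res = layout_model_gephi2(g, part, circle_radius=2.0)
        for x, y in res.coords.values():
            assert math.hypot(x, y) == pytest.approx(2.0, abs=1e-9)

    def test_single_module_gap0_equals_ring(self):
        g = nx.complete_graph(8)
        part = ModulePartition({n: "module_1" for n in g.nodes}, 0.0)
        res = layout_model_gephi2(g, part, circle_radius=1.0, gap_angle=0.0)
        from micronet.layouts import node_order

        expected = ring_positions(8, (0, 0), 1.0)
        for k, n in enumerate(node_order(g, list(g.nodes))):
            np.testing.assert_allclose(res.coords[n], expected[k], atol=1e-9)

    def test_arc_spans_proportional_to_size(self):
        g = nx.Graph()
        mapping = {f"a{i:02d}": "module_1" for i in range(30)}
        mapping.update({f"b{i:02d}": "module_2" for i in range(10)})
        g.add_nodes_from(mapping)
        part = ModulePartition(mapping, 0.0)
        res = layout_model_gephi2(g, part, gap_angle=0.0)
        ang = {n: math.atan2(y, x) % (2 * math.pi)
               for n, (x, y) in res.coords.items()}
        a_span = max(ang[f"a{i:02d}"] for i in range(30))
        # module_1 starts at angle 0; its 30 nodes span 3/4 of the circle
        # minus one node spacing
        step = 2 * math.pi * 0.75 / 30
        assert a_span == pytest.approx(2 * math.pi * 0.75 - step, abs=1e-9)


class TestModelIgraph:
    def test_two_node_equilibrium_near_k(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        area = 4.0
        k = math.sqrt(area / 2)
        dists = []
        for seed in range(5):
            res = layout_model_igraph(g, iterations=400, seed=seed,
                                      area=area)
            (x1, y1), (x2, y2) = res.coords["a"], res.coords["b"]
            dists.append(math.hypot(x1 - x2, y1 - y2))
        assert np.median(dists) == pytest.approx(k, rel=0.10)

    def test_bitwise_determinism(self):
        g = nx.gnp_random_graph(15, 0.3, seed=2)
        r1 = layout_model_igraph(g, seed=9)
        r2 = layout_model_igraph(g, seed=9)
        assert r1.coords == r2.coords

    @pytest.mark.parametrize("seed", range(1, 6))
    def test_disconnected_cliques_repel(self, seed):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        res = layout_model_igraph(g, iterations=300, seed=seed)
        pts = np.array([res.coords[n] for n in g.nodes])
        c1, c2 = pts[:4].mean(axis=0), pts[4:].mean(axis=0)
        diam1 = max(np.hypot(*(a - b))
                    for a, b in itertools.combinations(pts[:4], 2))
        diam2 = max(np.hypot(*(a - b))
                    for a, b in itertools.combinations(pts[4:], 2))
        assert math.hypot(*(c1 - c2)) > max(diam1, diam2)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            layout_model_igraph(nx.Graph())


class TestProgressivePacking:
    def test_single_circle_at_origin(self):
        (c,) = pack_circles_progressive([1.5])
        assert (c.cx, c.cy, c.radius) == (0.0, 0.0, 1.5)

    def test_two_circles_tangent_on_x_axis(self):
        a, b = pack_circles_progressive([1.0, 2.0])
        assert (b.cx, b.cy) == (3.0, 0.0)

    def test_three_equal_circles_equilateral(self):
        r = 0.8
        specs = pack_circles_progressive([r, r, r])
        pts = [(c.cx, c.cy) for c in specs]
        for a, b in itertools.combinations(pts, 2):
            assert math.hypot(a[0] - b[0], a[1] - b[1]) == pytest.approx(
                2 * r, abs=1e-9)

    def test_empty_input(self):
        assert pack_circles_progressive([]) == []

    @pytest.mark.parametrize("seed", range(4))
    def test_tangency_and_no_overlap(self, seed):
        rng = np.random.default_rng(seed)
        radii = rng.uniform(0.3, 2.0, 12)
        specs = pack_circles_progressive(radii)
        for i, c in enumerate(specs):
            if i == 0:
                continue
            gaps = [math.hypot(c.cx - o.cx, c.cy - o.cy) - c.radius - o.radius
                    for o in specs[:i]]
            assert min(gaps) >= -1e-6          # no overlap
            assert min(abs(gv) for gv in gaps) <= 1e-6  # touches someone


class TestMaptree:
    def test_single_module_inside_origin_circle(self):
        g = nx.complete_graph(9)
        part = ModulePartition({n: "module_1" for n in g.nodes}, 0.0)
        res = layout_model_maptree(g, part)
        r = res.modules.loc["module_1", "radius"]
        for x, y in res.coords.values():
            assert math.hypot(x, y) < r

    def test_nodes_strictly_inside_module_circle(self, modular_net):
        g, part = modular_net
        res = layout_model_maptree(g, part)
        for n, (x, y) in res.coords.items():
            row = res.modules.loc[part[n]]
            assert math.hypot(x - row.cx, y - row.cy) < row.radius

    @pytest.mark.parametrize("seed", range(3))
    def test_module_circles_non_overlapping(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.Graph()
        mapping = {}
        for k in range(int(rng.integers(2, 8))):
            for i in range(int(rng.integers(1, 20))):
                mapping[f"m{k}n{i:02d}"] = f"module_{k + 1}"
        g.add_nodes_from(mapping)
        part = ModulePartition(mapping, 0.0)
        res = layout_model_maptree(g, part)
        assert _pairwise_disc_separation(res) >= -1e-9


class TestDispatch:
    def test_registry_has_exactly_ten(self):
        assert len(LAYOUTS) == 10
        assert set(LAYOUTS) == {
            "randomClusterG", "PolygonClusterG", "PolygonRrClusterG",
            "ArtifCluster", "randSNEClusterG", "PolygonModsquareG",
            "PolyRdmNotdCirG", "model_Gephi.2", "model_igraph",
            "model_maptree"}

    def test_unknown_algorithm_lists_valid_names(self, modular_net):
        g, part = modular_net
        with pytest.raises(ValueError, match="model_maptree"):
            layout(g, part, "not_a_layout")

    @pytest.mark.parametrize("name", sorted(LAYOUTS))
    def test_every_layout_finite_and_deterministic(self, modular_net, name):
        g, part = modular_net
        kw = _kwargs_for(name)
        r1 = layout(g, part, name, **kw)
        r2 = layout(g, part, name, **kw)
        pts = np.array(list(r1.coords.values()))
        assert np.isfinite(pts).all()
        assert set(r1.coords) == set(g.nodes)
        assert r1.coords == r2.coords
        assert r1.algorithm == name

    @pytest.mark.parametrize("name", DISC_LAYOUTS)
    def test_disc_layouts_disjoint(self, modular_net, name):
        g, part = modular_net
        res = layout(g, part, name, **_kwargs_for(name))
        assert _pairwise_disc_separation(res) >= -1e-9

    @pytest.mark.parametrize(
        "fn,param", [(layout_polygon_cluster, "ring_radius"),
                     (layout_polygon_rr_cluster, "scale"),
                     (layout_poly_rdm_notd_cir, "scale"),
                     (layout_polygon_mod_square, "scale"),
                     (layout_model_maptree, "scale")])
    def test_scale_equivariance(self, modular_net, fn, param):
        g, part = modular_net
        kw = {"seed": 3} if "seed" in inspect.signature(fn).parameters else {}
        r1 = fn(g, part, **{param: 1.0}, **kw)
        r3 = fn(g, part, **{param: 3.0}, **kw)
        for n in g.nodes:
            np.testing.assert_allclose(np.array(r3.coords[n]),
                                       3.0 * np.array(r1.coords[n]),
                                       atol=1e-9)
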