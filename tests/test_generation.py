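import math

import numpy as np
import pytest

from pialflow.fixtures import FixtureConfig, synth_pial
from pialflow.generation import (GenerationConfig, assemble_network, build_network,
                                 generate_capillary_lattice,
                                 generate_penetrating_tree, place_av_roots,
                                 refine_pial_network)
from pialflow.network import validate_network


@pytest.fixture(scope="module")
def pial():
    return synth_pial(FixtureConfig(rng_seed=3), np.random.default_rng(3))


@pytest.fixture(scope="module")
def gen_cfg():
    return GenerationConfig()


class TestRefinePialNetwork:
    def test_root_count_matches_density_times_hull_area(self, pial, gen_cfg):
        from shapely.geometry import MultiPoint

        refined = refine_pial_network(pial, gen_cfg, np.random.default_rng(0))
        hull = MultiPoint([(v.position[0], v.position[1])
                           for v in pial.vertices.values()]).convex_hull
        expected = round(gen_cfg.target_da_root_density * hull.area / 1e6)
        assert len(refined.vertices_of_role("da_root")) == expected

    def test_noop_when_target_already_met(self, pial):
        cfg = GenerationConfig(target_da_root_density=1e-9)
        refined = refine_pial_network(pial, cfg, np.random.default_rng(0))
        assert len(refined.vertices_of_role("da_root")) == 0
        assert set(refined.vessels) == set(pial.vessels)

    def test_original_edges_preserved(self, pial, gen_cfg):
        refined = refine_pial_network(pial, gen_cfg, np.random.default_rng(0))
        # original ids survive (edges may be split, never removed)
        assert set(pial.vessels) <= set(refined.vessels)

    def test_every_root_reaches_inflow_over_sa_edges(self, pial, gen_cfg):
        import networkx as nx

        refined = refine_pial_network(pial, gen_cfg, np.random.default_rng(0))
        g = nx.Graph()
        for e in refined.vessels_of_type("SA", "SA_to_CoW", "LMC"):
            g.add_edge(e.v1, e.v2)
        cow = refined.inflow_vertex.id
        for root in refined.vertices_of_role("da_root"):
            assert nx.has_path(g, cow, root.id)

    def test_unreachable_density_raises(self, pial):
        cfg = GenerationConfig(target_da_root_density=5000.0,
                               da_root_min_spacing=300.0)
        with pytest.raises(ValueError, match="spacing"):
            refine_pial_network(pial, cfg, np.random.default_rng(0))


class TestPlaceAvRoots:
    def test_av_count_is_ratio_times_da_count(self, pial, gen_cfg):
        refined = refine_pial_network(pial, gen_cfg, np.random.default_rng(0))
        n_da = len(refined.vertices_of_role("da_root"))
        for ratio in (1, 3):
            cfg = GenerationConfig(av_per_da=ratio)
            out = place_av_roots(refined, cfg, np.random.default_rng(1))
            assert len(out.vertices_of_role("av_root")) == ratio * n_da

    def test_av_roots_at_configured_offset(self, pial, gen_cfg):
        refined = refine_pial_network(pial, gen_cfg, np.random.default_rng(0))
        out = place_av_roots(refined, gen_cfg, np.random.default_rng(1))
        roots = np.array([v.position[:2] for v in out.vertices_of_role("da_root")])
        for av in out.vertices_of_role("av_root"):
            dists = np.linalg.norm(roots - av.position[:2], axis=1)
            # the parent DA root sits exactly one offset radius away
            assert np.min(np.abs(dists - gen_cfg.av_offset)) < 1e-6


class TestPenetratingTree:
    def _root(self, net_cls):
        from pialflow.network import Vertex

        return Vertex(0, np.array([500.0, 500.0, 0.0]), "da_root")

    def test_murray_rule_at_every_bifurcation(self, gen_cfg):
        frag = generate_penetrating_tree(self._root(None), "DA", gen_cfg,
                                         np.random.default_rng(5))
        adj = frag.adjacency()
        for vid, edges in adj.items():
            pos_z = frag.vertices[vid].position[2]
            children = [e for e in edges if frag.vertices[
                e.v2 if e.v1 == vid else e.v1].position[2] > pos_z]
            parents = [e for e in edges if e not in children]
            if len(children) == 2 and len(parents) == 1:
                d_p = parents[0].diameter
                lhs = d_p**3
                rhs = sum(c.diameter**3 for c in children)
                assert abs(lhs - rhs) / lhs < 0.10

    def test_depth_bounded_by_lattice_depth(self, gen_cfg):
        for seed in range(5):
            frag = generate_penetrating_tree(self._root(None), "DA", gen_cfg,
                                             np.random.default_rng(seed))
            zs = [v.position[2] for v in frag.vertices.values()]
            assert min(zs) >= 0.0 and max(zs) <= gen_cfg.lattice_depth + 1e-9

    def test_leaves_marked(self, gen_cfg):
        frag = generate_penetrating_tree(self._root(None), "AV", gen_cfg,
                                         np.random.default_rng(2))
        leaves = frag.vertices_of_role("tree_leaf")
        assert leaves, "tree must terminate in leaves"

    def test_deterministic_per_seed(self, gen_cfg):
        a = generate_penetrating_tree(self._root(None), "DA", gen_cfg,
                                      np.random.default_rng(9))
        b = generate_penetrating_tree(self._root(None), "DA", gen_cfg,
                                      np.random.default_rng(9))
        assert len(a.vertices) == len(b.vertices)
        for vid in a.vertices:
            assert np.array_equal(a.vertices[vid].position, b.vertices[vid].position)
        for eid in a.vessels:
            assert a.vessels[eid].diameter == b.vessels[eid].diameter

    def test_invalid_kind_rejected(self, gen_cfg):
        with pytest.raises(ValueError):
            generate_penetrating_tree(self._root(None), "C", gen_cfg,
                                      np.random.default_rng(0))


class TestCapillaryLattice:
    def test_uniform_length_and_tortuosity(self, gen_cfg):
        frag = generate_capillary_lattice((0, 500, 0, 500), gen_cfg,
                                          np.random.default_rng(0))
        chord_target = gen_cfg.capillary_length / gen_cfg.capillary_tortuosity
        for e in frag.vessels.values():
            assert e.length == pytest.approx(62.0)
            chord = frag.distance(e.v1, e.v2)
            assert chord == pytest.approx(chord_target, rel=1e-9)

    def test_tortuosity_one_gives_straight_edges(self):
        cfg = GenerationConfig(capillary_tortuosity=1.0)
        frag = generate_capillary_lattice((0, 400, 0, 400), cfg,
                                          np.random.default_rng(0))
        e = next(iter(frag.vessels.values()))
        assert frag.distance(e.v1, e.v2) == pytest.approx(e.length)

    def test_uniform_diameters(self, gen_cfg):
        frag = generate_capillary_lattice((0, 400, 0, 400), gen_cfg,
                                          np.random.default_rng(0))
        assert {e.diameter for e in frag.vessels.values()} == {4.0}

    def test_bbox_smaller_than_hexagon_rejected(self, gen_cfg):
        with pytest.raises(ValueError, match="hexagon"):
            generate_capillary_lattice((0, 30, 0, 30), gen_cfg,
                                       np.random.default_rng(0))

    def test_in_plane_interior_degree_three(self, gen_cfg):
        cfg = GenerationConfig(lattice_layers=1)
        frag = generate_capillary_lattice((0, 600, 0, 600), cfg,
                                          np.random.default_rng(0))
        degs = {}
        for e in frag.vessels.values():
            degs[e.v1] = degs.get(e.v1, 0) + 1
            degs[e.v2] = degs.get(e.v2, 0) + 1
        assert max(degs.values()) == 3


class TestAssembledNetwork:
    def test_single_inflow_with_100_mmHg(self, fixture_net):
        cow = fixture_net.inflow_vertex
        assert fixture_net.boundary_conditions[cow.id] == 100.0

    def test_every_av_root_has_10_mmHg_outflow(self, fixture_net):
        for v in fixture_net.vertices_of_role("av_root"):
            assert fixture_net.boundary_conditions[v.id] == 10.0

    def test_hierarchical_path_cow_sa_da_c_av(self, fixture_net):
        # blood can run CoW -> SA -> DA -> C -> AV following the type order
        order = {"SA_to_CoW": 0, "SA": 1, "LMC": 1, "DA": 2, "C": 3, "AV": 4}
        adj = fixture_net.adjacency()
        stage = {fixture_net.inflow_vertex.id: 0}
        stack = [fixture_net.inflow_vertex.id]
        while stack:
            u = stack.pop()
            for e in adj[u]:
                s = order[e.vtype]
                if s >= stage[u] - 0:  # allowed to stay or go downstream
                    w = e.v2 if e.v1 == u else e.v1
                    ns = max(stage[u], s)
                    if w not in stage or ns < stage[w]:
                        stage[w] = ns
                        stack.append(w)
        reached_av = [v.id for v in fixture_net.vertices_of_role("av_root")
                      if v.id in stage]
        assert reached_av, "no AV root reachable through the vessel hierarchy"

    def test_regeneration_bit_identical(self):
        from pialflow.fixtures import default_fixture

        a = default_fixture(seed=11)
        b = default_fixture(seed=11)
        assert set(a.vessels) == set(b.vessels)
        for eid in a.vessels:
            ea, eb = a.vessels[eid], b.vessels[eid]
            assert (ea.v1, ea.v2, ea.vtype) == (eb.v1, eb.v2, eb.vtype)
            assert ea.diameter == eb.diameter and ea.length == eb.length
        for vid in a.vertices:
            assert np.array_equal(a.vertices[vid].position, b.vertices[vid].position)

    def test_connector_too_long_raises(self, pial):
        cfg = GenerationConfig(max_connector_length=1.0)
        with pytest.raises(ValueError, match="connector"):
            build_network(pial, cfg, np.random.default_rng(0))
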