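"""CCO: viscosity, resistance, radius rebalancing, cost, and optimization."""

import math

import numpy as np
import pytest

from vasctree.cco import (
    CCOConfig,
    add_leaf,
    candidate_edges,
    edge_resistance,
    generate,
    optimize_bifurcation,
    rebalance_radii,
    tree_cost,
    viscosity,
)
from vasctree.domain import Sphere
from vasctree.synth import SyntheticPopulationSpec, make_seed_edge, make_tree

from conftest import build_tree


class TestViscosity:
    def test_doubling_point(self):
        # delta/r = 1 gives 4 * mu_inf
        assert viscosity(4.29) == pytest.approx(16.0, abs=1e-12)

    def test_constant_regime(self):
        assert viscosity(160.0) == 4.0
        assert viscosity(500.0) == 4.0

    def test_value_and_continuity_at_140(self):
        assert viscosity(140.0) == pytest.approx(4.0 * (1 + 4.29 / 140) ** 2, abs=1e-12)
        below = viscosity(np.nextafter(140.0, 0.0))
        above = viscosity(np.nextafter(140.0, 200.0))
        assert abs(below - above) < 1e-12
        below = viscosity(np.nextafter(160.0, 0.0))
        assert abs(below - 4.0) < 1e-12

    def test_clamped_below_4um(self):
        assert viscosity(1.0) == viscosity(4.0)

    def test_monotone_nonincreasing(self):
        r = np.linspace(1.0, 300.0, 4000)
        mu = viscosity(r)
        assert np.all(np.diff(mu) <= 1e-12)

    def test_nonpositive_radius_is_an_error(self):
        with pytest.raises(ValueError):
            viscosity(0.0)


class TestEdgeResistance:
    def test_direct_value(self):
        # l = 1 mm, r = 1 mm, mu = 4e-3 Pa s
        R = edge_resistance(1.0, 1.0, "constant")
        assert R == pytest.approx(8 * 4e-3 * 1e-3 / (math.pi * 1e-12), rel=1e-12)
        assert R == pytest.approx(1.0186e7, rel=1e-4)

    def test_fourth_power_scaling(self):
        assert edge_resistance(1.0, 1.0, "constant") / edge_resistance(
            1.0, 2.0, "constant") == pytest.approx(16.0)

    def test_trivial_edge_has_zero_resistance(self):
        assert edge_resistance(0.0, 1.0) == 0.0

    def test_bad_radius(self):
        with pytest.raises(ValueError):
            edge_resistance(1.0, 0.0)


class TestRebalance:
    def test_symmetric_bifurcation(self, one_bifurcation_tree):
        cfg = CCOConfig(viscosity_model="constant")
        fs = rebalance_radii(one_bifurcation_tree, cfg)
        assert fs.radius["e1"] == pytest.approx(2 ** (-1 / 3), rel=1e-10)
        assert fs.radius["e2"] == pytest.approx(2 ** (-1 / 3), rel=1e-10)

    def test_length_16_vs_1_closed_form(self):
        # equal flows, l1/r1^4 = l2/r2^4 with r1^3 + r2^3 = 1 -> r1 = 2 r2
        t = build_tree(
            {"r": (0, 0, 0), "a": (0, 0, -10), "b": (0, 0, -26), "c": (1, 0, -10)},
            [("e0", "r", "a", 1.0), ("e1", "a", "b", 0.5), ("e2", "a", "c", 0.5)],
            "r",
        )
        fs = rebalance_radii(t, CCOConfig(viscosity_model="constant"))
        assert fs.radius["e2"] == pytest.approx(9 ** (-1 / 3), rel=1e-9)
        assert fs.radius["e1"] == pytest.approx(2 * 9 ** (-1 / 3), rel=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_equal_leaf_pressure_drops(self, seed):
        rng = np.random.Generator(np.random.MT19937(seed))
        t = make_tree(SyntheticPopulationSpec(leaf_range=(10, 40), seed=seed), rng)
        fs = rebalance_radii(t, CCOConfig())
        drops = np.array(list(fs.leaf_pressure_drop.values()))
        assert (drops.max() - drops.min()) / drops.max() < 1e-6
        # independent recomputation of one leaf's drop from R and Q
        t2 = t.copy()
        for eid, r in fs.radius.items():
            t2.edges[eid].radius = r
        leaf = t2.leaf_edges()[0]
        drop = 0.0
        eid = leaf
        while eid is not None:
            drop += fs.flow[eid] * CCOConfig().leaf_flow * fs.resistance[eid]
            eid = t2.parent(eid)
        assert drop == pytest.approx(fs.leaf_pressure_drop[leaf], rel=1e-9)

    def test_gamma_law_holds(self, small_population):
        t = small_population[0]
        fs = rebalance_radii(t, CCOConfig())
        for eid in t.edges:
            ds = t.daughters(eid)
            if ds:
                rp = fs.radius[eid]
                r1, r2 = fs.radius[ds[0]], fs.radius[ds[1]]
                assert r1**3 + r2**3 == pytest.approx(rp**3, rel=1e-9)

    def test_flow_conservation_exact(self, small_population):
        t = small_population[1]
        fs = rebalance_radii(t, CCOConfig())
        for eid in t.edges:
            ds = t.daughters(eid)
            if ds:
                assert fs.flow[eid] == fs.flow[ds[0]] + fs.flow[ds[1]]

    def test_fixed_pressure_drop_mode(self, one_bifurcation_tree):
        cfg = CCOConfig(root_condition="fixed_pressure_drop", pressure_drop=1000.0,
                        viscosity_model="constant")
        fs = rebalance_radii(one_bifurcation_tree, cfg)
        drops = list(fs.leaf_pressure_drop.values())
        assert drops[0] == pytest.approx(1000.0, rel=1e-6)


class TestCostAndCandidates:
    def test_single_interior_edge(self):
        t = build_tree({"r": (0, 0, -20), "a": (0, 0, -30)},
                       [("e", "r", "a", 1.0)], "r")
        dom = Sphere(center=(0, 0, -25), radius=50.0)
        assert tree_cost(t, dom) == pytest.approx(10.0)

    def test_penalty_term(self):
        # one endpoint 2 mm outside the sphere
        t = build_tree({"r": (0, 0, 52), "a": (0, 0, 42)},
                       [("e", "r", "a", 1.0)], "r")
        dom = Sphere(center=(0, 0, 0), radius=50.0)
        assert tree_cost(t, dom) == pytest.approx(10.0 + 42.0 * 4.0)

    def test_lambda_zero_gives_total_length(self):
        t = build_tree({"r": (0, 0, 0), "a": (0, 0, -10)},
                       [("e", "r", "a", 2.0)], "r")
        cfg = CCOConfig(lambda_exponent=1e-12)  # lambda -> 0 limit
        assert tree_cost(t, None, cfg) == pytest.approx(10.0, rel=1e-9)

    def test_zero_penalty_equals_volume_term(self, small_population):
        t = small_population[2]
        cfg = CCOConfig(penalty_C=0.0)
        dom = Sphere(center=(0, 0, 0), radius=1.0)  # everything far outside
        expect = sum(t.length(e) * t.edges[e].radius ** 2 for e in t.edges)
        assert tree_cost(t, dom, cfg) == pytest.approx(expect)

    def test_candidates_on_one_edge_tree(self):
        t = make_seed_edge()
        assert candidate_edges(t, (5, 5, 5), k=40) == ["e0"]

    def test_candidates_match_exhaustive_sort(self):
        rng = np.random.Generator(np.random.MT19937(13))
        t = make_tree(SyntheticPopulationSpec(leaf_range=(120, 120), seed=13), rng)
        p = (3.0, -2.0, -15.0)
        got = candidate_edges(t, p, k=25)
        mids = {
            eid: 0.5 * (t.nodes[t.edges[eid].initial].position
                        + t.nodes[t.edges[eid].terminal].position)
            for eid in t.edges
        }
        expect = sorted(t.edges, key=lambda e: (np.linalg.norm(mids[e] - p), e))[:25]
        assert got == expect


class TestOptimization:
    def test_descent_never_worse_than_midpoint(self, one_bifurcation_tree):
        dom = Sphere(center=(0, 0, -10), radius=30.0)
        cfg = CCOConfig(viscosity_model="constant")
        new_leaf = (4.0, 3.0, -8.0)
        pos, cost = optimize_bifurcation(one_bifurcation_tree, "e0", new_leaf,
                                         config=cfg, domain=dom)
        # cost at the starting midpoint, computed via a fresh 0-step descent
        _, cost0 = optimize_bifurcation(one_bifurcation_tree, "e0", new_leaf,
                                        config=CCOConfig(
                                            viscosity_model="constant",
                                            max_gd_iterations=0),
                                        domain=dom)
        assert cost <= cost0 + 1e-12

    def test_symmetric_configuration_stays_on_symmetry_plane(self):
        # tree and new leaf symmetric under y -> -y: optimum has y ~ 0
        t = build_tree(
            {"r": (0, 0, 10), "a": (0, 0, 0)},
            [("e0", "r", "a", 1.0)],
            "r",
        )
        dom = Sphere(center=(0, 0, -5), radius=40.0)
        cfg = CCOConfig(viscosity_model="constant", final_tolerance=1e-4)
        pos, _ = optimize_bifurcation(t, "e0", (6.0, 0.0, -4.0),
                                      config=cfg, domain=dom)
        assert abs(pos[1]) < 1e-3

    def test_add_leaf_structure(self, one_bifurcation_tree):
        dom = Sphere(center=(0, 0, -10), radius=30.0)
        cfg = CCOConfig(viscosity_model="constant", n_candidates=3, n_shortlist=2)
        grown, audit = add_leaf(one_bifurcation_tree, (6.0, 2.0, -12.0),
                                config=cfg, domain=dom)
        assert grown.n_leaves() == one_bifurcation_tree.n_leaves() + 1
        assert len(grown.edges) == len(one_bifurcation_tree.edges) + 2
        assert audit["committed_cost"] == min(audit["final_costs"].values())

    def test_add_leaf_matches_exhaustive_candidate_search(self):
        rng = np.random.Generator(np.random.MT19937(17))
        t = make_tree(SyntheticPopulationSpec(leaf_range=(3, 3), seed=17), rng)
        fs = rebalance_radii(t, CCOConfig(viscosity_model="constant"))
        for eid, r in fs.radius.items():
            t.edges[eid].radius = r
        dom = Sphere(center=(0, 0, -10), radius=60.0)
        point = (4.0, 4.0, -9.0)
        cfg = CCOConfig(viscosity_model="constant", n_candidates=5, n_shortlist=5)
        grown, audit = add_leaf(t, point, config=cfg, domain=dom)
        best = min(audit["final_costs"], key=lambda e: audit["final_costs"][e])
        assert audit["committed_edge"] == best
        # exhaustive: every edge fully optimized independently
        costs = {
            eid: optimize_bifurcation(t, eid, point, config=cfg, domain=dom)[1]
            for eid in t.edges
        }
        assert min(costs, key=lambda e: (costs[e], e)) == audit["committed_edge"]


class TestGenerate:
    def test_zero_targets_is_identity(self):
        seed = make_seed_edge()
        out, audit = generate(seed, None, np.empty((0, 3)), CCOConfig())
        assert audit == []
        assert set(out.edges) == set(seed.edges)

    def test_same_seed_bit_identical(self):
        from vasctree.domain import sample_leaf_targets
        from vasctree.synth import tree_checksum

        dom = Sphere(center=(0, 0, -30), radius=15.0)
        seed = make_seed_edge(end=(0, 0, -16))
        cfg = CCOConfig(n_candidates=6, n_shortlist=3)
        targets = sample_leaf_targets(dom, 8, 3.0, seed=5)
        a, _ = generate(seed, dom, targets, cfg)
        b, _ = generate(seed, dom, targets, cfg)
        assert tree_checksum(a) == tree_checksum(b)

    def test_small_generation_invariants(self):
        from vasctree.domain import sample_leaf_targets

        dom = Sphere(center=(0, 0, -30), radius=15.0)
        seed = make_seed_edge(end=(0, 0, -16))
        targets = sample_leaf_targets(dom, 10, 3.0, seed=6)
        cfg = CCOConfig(n_candidates=8, n_shortlist=4)
        tree, audit = generate(seed, dom, targets, cfg)
        assert tree.n_leaves() == 11
        for eid in tree.edges:
            ds = tree.daughters(eid)
            if ds:
                rp = tree.edges[eid].radius
                r1, r2 = (tree.edges[d].radius for d in ds)
                assert r1**3 + r2**3 == pytest.approx(rp**3, rel=1e-8)
        # generated bifurcations sit essentially inside the convex domain:
        # the soft penalty balances the volume gradient (~r^2) against
        # 2 C d, so equilibrium offsets stay below ~r^2/(2C) ~ 0.05 mm
        for nid, node in tree.nodes.items():
            if nid.startswith("g"):
                assert dom.distance1(node.position) < 0.05
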