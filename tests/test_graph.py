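"""Spanning trees, Matrix-Tree steady states, cycles and detailed balance."""

import itertools
import math

import numpy as np
import pytest

from tfreciprocity import (
    Edge,
    EquilibriumLocusParams,
    RateGraph,
    build_pair_graph,
    cycle_ratio,
    enumerate_rooted_spanning_trees,
    equilibrium_probabilities,
    free_energy_delta,
    is_detailed_balanced,
    steady_state,
    zeta,
)
from tfreciprocity.graph import steady_state_nullspace, tree_weight

from conftest import random_reversible_graph


def two_state_graph(k_bind=3.0, k_unbind=2.0) -> RateGraph:
    return RateGraph(
        vertices=["nb", "b"],
        edges=[Edge("nb", "b", rate=k_bind), Edge("b", "nb", rate=k_unbind)],
    )


def triangle() -> RateGraph:
    edges = []
    for u, v in itertools.permutations("abc", 2):
        edges.append(Edge(u, v, rate=1.0))
    return RateGraph(vertices=list("abc"), edges=edges)


class TestSpanningTrees:
    def test_locus_cycle_has_four_trees_rooted_at_e(self, fig2d):
        g = build_pair_graph(fig2d)
        trees = enumerate_rooted_spanning_trees(g, "e")
        assert len(trees) == 4
        # the four label products are the terms of the rooted-tree expansion:
        # k2- k4- k3+[O], k1- k2- k4-, k1- k2- k3-, k1- k3- k4+[S]
        products = sorted(tree_weight(g, t) for t in trees)
        assert products == sorted([4 * 1 * 6, 2 * 4 * 1, 2 * 4 * 2, 2 * 2 * 6])

    def test_tree_structure_invariants(self, fig2d):
        g = build_pair_graph(fig2d)
        for root in g.vertices:
            for tree in enumerate_rooted_spanning_trees(g, root):
                sources = [u for u, _ in tree]
                touched = set(sources) | {v for _, v in tree}
                assert touched == set(g.vertices)
                assert len(tree) == len(g.vertices) - 1
                assert root not in sources  # root has no outgoing edge
                assert len(set(sources)) == len(sources)

    def test_two_state_graph_has_single_tree(self):
        g = two_state_graph()
        assert enumerate_rooted_spanning_trees(g, "b") == [frozenset({("nb", "b")})]

    def test_triangle_tree_count_matches_brute_force(self):
        g = triangle()
        # oracle: all edge subsets of size 2 forming a spanning root-directed tree
        for root in g.vertices:
            all_edges = [(e.source, e.target) for e in g.edges]
            expected = set()
            for sub in itertools.combinations(all_edges, 2):
                sources = [u for u, _ in sub]
                if root in sources or len(set(sources)) != 2:
                    continue
                succ = dict(sub)
                if all(
                    succ.get(succ.get(v, root), root) == root or succ[v] == root
                    for v in succ
                ):
                    expected.add(frozenset(sub))
            got = set(enumerate_rooted_spanning_trees(g, root))
            assert got == expected
            assert len(got) == 3

    def test_unknown_root_raises_with_name(self, fig2d):
        g = build_pair_graph(fig2d)
        with pytest.raises(ValueError, match="nope"):
            enumerate_rooted_spanning_trees(g, "nope")


class TestZeta:
    def test_printed_expansion_value(self, fig2d):
        g = build_pair_graph(fig2d)
        assert zeta(g, "e") == pytest.approx(72.0, rel=1e-12)

    def test_zeta_sum_over_vertices(self, fig2d):
        g = build_pair_graph(fig2d)
        assert sum(zeta(g, v) for v in g.vertices) == pytest.approx(558.0, rel=1e-12)

    def test_determinant_matches_tree_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            g = random_reversible_graph(rng)
            v = g.vertices[int(rng.integers(len(g.vertices)))]
            by_trees = sum(
                tree_weight(g, t) for t in enumerate_rooted_spanning_trees(g, v)
            )
            assert zeta(g, v) == pytest.approx(by_trees, rel=1e-9)

    def test_two_state_zeta_is_binding_label(self):
        g = two_state_graph(k_bind=5.5)
        assert zeta(g, "b") == pytest.approx(5.5)


class TestSteadyState:
    def test_fig2d_empty_state_probability(self, fig2d):
        ss = steady_state(build_pair_graph(fig2d))
        assert ss["e"] == pytest.approx(4 / 31, rel=1e-12)

    def test_two_state_kappa_form(self):
        for kappa in (0.042, 1.0, 7.3):
            g = two_state_graph(k_bind=kappa, k_unbind=1.0)
            assert steady_state(g)["b"] == pytest.approx(kappa / (1 + kappa))

    def test_symmetric_graph_is_uniform(self):
        ss = steady_state(triangle())
        for v in "abc":
            assert ss[v] == pytest.approx(1 / 3, rel=1e-12)

    def test_matches_nullspace_oracle_on_random_graphs(self):
        """Matrix-Tree route vs dense null-space solve on >=100 random graphs."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            g = random_reversible_graph(rng)
            ss = steady_state(g)
            oracle = steady_state_nullspace(g)
            for v in g.vertices:
                assert ss[v] == pytest.approx(oracle[v], rel=1e-10, abs=1e-12)

    def test_stationarity_of_probability_flux(self, fig2e):
        g = build_pair_graph(fig2e)
        ss = steady_state(g)
        values = g.edge_values()
        for v in g.vertices:
            influx = sum(a * ss[u] for (u, w), a in values.items() if w == v)
            outflux = sum(a * ss[v] for (u, w), a in values.items() if u == v)
            assert influx == pytest.approx(outflux, rel=1e-10)

    def test_zero_concentration_restricts_support(self, fig2d):
        g = build_pair_graph(fig2d.with_concentrations(conc_O=0.0))
        ss = steady_state(g)
        assert ss["o"] == 0.0 and ss["so"] == 0.0
        assert ss["s"] == pytest.approx(1.5 / 2.5)

    def test_all_zero_zetas_raise(self):
        g = RateGraph(
            vertices=["a", "b"],
            edges=[
                Edge("a", "b", on_rate=1.0, species="X"),
                Edge("b", "a", on_rate=1.0, species="X"),
            ],
            concentrations={"X": 0.0},
        )
        with pytest.raises(ValueError, match="steady state"):
            steady_state(g)


class TestCyclesAndDetailedBalance:
    CYCLE = ["e", "s", "so", "o", "e"]

    def test_equilibrium_cycle_ratio_is_one(self, fig2d):
        g = build_pair_graph(fig2d)
        assert cycle_ratio(g, self.CYCLE) == pytest.approx(1.0, rel=1e-12)

    def test_nonequilibrium_cycle_ratio(self, fig2e):
        g = build_pair_graph(fig2e)
        assert cycle_ratio(g, self.CYCLE) == pytest.approx(12.0, rel=1e-12)

    def test_concentration_rescaling_leaves_ratio_unchanged(self, fig2e):
        g1 = build_pair_graph(fig2e)
        g2 = build_pair_graph(fig2e.with_concentrations(conc_S=3.7, conc_O=3.7))
        assert cycle_ratio(g1, self.CYCLE) == pytest.approx(
            cycle_ratio(g2, self.CYCLE), rel=1e-12
        )

    def test_missing_edge_error_names_the_pair(self, fig2d):
        g = build_pair_graph(fig2d)
        with pytest.raises(KeyError, match="e.*so"):
            cycle_ratio(g, ["e", "so", "e"])

    def test_detailed_balance_verdicts(self, fig2d, fig2e):
        balanced, _ = is_detailed_balanced(build_pair_graph(fig2d))
        broken, worst = is_detailed_balanced(build_pair_graph(fig2e))
        assert balanced and not broken and worst > 0.1

    def test_tree_topology_always_balances(self):
        g = RateGraph(
            vertices=["a", "b", "c"],
            edges=[
                Edge("a", "b", rate=2.0),
                Edge("b", "a", rate=5.0),
                Edge("b", "c", rate=0.3),
                Edge("c", "b", rate=9.0),
            ],
        )
        assert is_detailed_balanced(g)[0]

    def test_kolmogorov_equivalence_on_random_graphs(self):
        """Edgewise flux balance iff every fundamental cycle has ratio 1."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            g = random_reversible_graph(rng)
            balanced, _ = is_detailed_balanced(g, tol=1e-9)
            cycles_ok = _all_fundamental_cycles_unit(g)
            assert balanced == cycles_ok

    def test_path_independence_at_equilibrium(self, fig2d):
        """Label-ratio products between fixed endpoints are path-independent."""
        g = build_pair_graph(fig2d)
        values = g.edge_values()

        def path_product(path):
            out = 1.0
            for u, v in zip(path[:-1], path[1:]):
                out *= values[(u, v)] / values[(v, u)]
            return out

        assert path_product(["e", "s", "so"]) == pytest.approx(
            path_product(["e", "o", "so"]), rel=1e-12
        )


def _all_fundamental_cycles_unit(g: RateGraph, tol: float = 1e-9) -> bool:
    # fundamental cycles from a BFS tree over the undirected skeleton
    values = g.edge_values()
    adj = {}
    for u, v in values:
        adj.setdefault(u, set()).add(v)
    root = g.vertices[0]
    parent = {root: None}
    order = [root]
    for u in order:
        for v in sorted(adj[u]):
            if v not in parent:
                parent[v] = u
                order.append(v)

    def path_to_root(v):
        out = [v]
        while parent[out[-1]] is not None:
            out.append(parent[out[-1]])
        return out

    seen = set()
    for u, v in values:
        if (v, u) in seen or parent.get(v) == u or parent.get(u) == v:
            continue
        seen.add((u, v))
        pu, pv = path_to_root(u), path_to_root(v)
        common = set(pu) & set(pv)
        anc = next(x for x in pu if x in common)
        cyc = pu[: pu.index(anc) + 1] + list(reversed(pv[: pv.index(anc)])) + [u]
        ratio = cycle_ratio(g, list(reversed(cyc)))
        if abs(ratio - 1.0) > tol:
            return False
    return True


class TestEquilibriumClosedForms:
    def test_matches_matrix_tree_on_equilibrium_table(self, fig2d):
        params = EquilibriumLocusParams(K_S=1.5, K_O=0.75, omega=4.0, K_O_i=0.75)
        eq = equilibrium_probabilities(params)
        ss = steady_state(build_pair_graph(fig2d))
        for v in ("e", "s", "o", "so"):
            assert eq[v] == pytest.approx(ss[v], rel=1e-12)
        assert eq["e"] == pytest.approx(1 / 7.75)
        assert eq["so"] == pytest.approx(4.5 / 7.75)

    def test_differs_from_matrix_tree_off_equilibrium(self, fig2e):
        # the closed form presumes the cycle condition; fig2E violates it
        params = EquilibriumLocusParams(K_S=1.5, K_O=0.75, omega=4.0, K_O_i=0.75)
        ss = steady_state(build_pair_graph(fig2e))
        assert equilibrium_probabilities(params)["so"] != pytest.approx(
            ss["so"], rel=1e-3
        )

    def test_empty_dna_limit(self):
        params = EquilibriumLocusParams(K_S=1e-12, K_O=1e-12, omega=1.0)
        assert equilibrium_probabilities(params)["e"] == pytest.approx(1.0)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            EquilibriumLocusParams(K_S=-1.0, K_O=1.0, omega=1.0)


class TestFreeEnergy:
    @pytest.mark.parametrize(
        "ratio,expected", [(1.0, 0.0), (math.e, 1.0), (7.389056, 2.0)]
    )
    def test_log_of_label_ratio(self, ratio, expected):
        assert free_energy_delta(ratio) == pytest.approx(expected, abs=1e-6)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            free_energy_delta(0.0)


class TestGraphIO:
    def test_json_round_trip_is_lossless(self, tmp_path, fig2d):
        g = build_pair_graph(fig2d)
        path = tmp_path / "locus.json"
        g.to_json(path)
        g2 = RateGraph.from_json(path)
        assert g2.to_dict() == g.to_dict()
        assert steady_state(g2)["e"] == pytest.approx(steady_state(g)["e"])

    def test_irreversible_edge_rejected(self):
        with pytest.raises(ValueError, match="reverse"):
            RateGraph(vertices=["a", "b"], edges=[Edge("a", "b", rate=1.0)])
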