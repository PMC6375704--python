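"""Product graphs, the additivity lemma, and mixture reciprocity."""

import numpy as np
import pytest

from tfreciprocity import (
    Edge,
    EquilibriumLocusParams,
    GenomeMixture,
    RateGraph,
    average_occupancy,
    build_pair_graph,
    diversity_gamma,
    diversity_surface,
    equilibrium_type_fractions,
    generate_locus_model,
    mixture_fraction,
    product_graph,
    single_locus_fraction,
    steady_state,
)

from conftest import random_reversible_graph

ETA_S = {"e": 0, "o": 0, "s": 1, "so": 1}


def two_state(k_bind, k_unbind):
    return RateGraph(
        vertices=["nb", "b"],
        edges=[Edge("nb", "b", rate=k_bind), Edge("b", "nb", rate=k_unbind)],
    )


class TestProductGraph:
    def test_two_state_product_factorizes(self):
        g1, g2 = two_state(3.0, 2.0), two_state(0.5, 4.0)
        prod = product_graph(g1, g2)
        assert len(prod.vertices) == 4
        ss = steady_state(prod)
        s1, s2 = steady_state(g1), steady_state(g2)
        for i in g1.vertices:
            for j in g2.vertices:
                assert ss[(i, j)] == pytest.approx(s1[i] * s2[j], rel=1e-10)

    def test_single_vertex_is_identity_element(self, fig2d):
        g = build_pair_graph(fig2d)
        one = RateGraph(vertices=["*"], edges=[])
        prod = product_graph(g, one)
        ss = steady_state(prod)
        base = steady_state(g)
        for v in g.vertices:
            assert ss[(v, "*")] == pytest.approx(base[v], rel=1e-10)

    def test_factorization_holds_off_equilibrium(self, fig2d, fig2e):
        """The lemma needs no detailed balance in either factor."""
        g1, g2 = build_pair_graph(fig2d), build_pair_graph(fig2e)
        prod = product_graph(g1, g2)
        assert len(prod.vertices) == 16
        ss = steady_state(prod)
        s1, s2 = steady_state(g1), steady_state(g2)
        for i in g1.vertices:
            for j in g2.vertices:
                assert ss[(i, j)] == pytest.approx(s1[i] * s2[j], rel=1e-8)

    def test_factorization_on_random_graphs(self):
        rng = np.random.default_rng(19)
        for _ in range(5):
            g1 = random_reversible_graph(rng, n_max=4)
            g2 = random_reversible_graph(rng, n_max=4)
            ss = steady_state(product_graph(g1, g2))
            s1, s2 = steady_state(g1), steady_state(g2)
            for i in g1.vertices:
                for j in g2.vertices:
                    assert ss[(i, j)] == pytest.approx(
                        s1[i] * s2[j], rel=1e-8, abs=1e-12
                    )


class TestAverageOccupancy:
    def test_single_locus_bound_fraction(self, fig2d):
        ss = steady_state(build_pair_graph(fig2d))
        assert average_occupancy(ss, ETA_S) == pytest.approx(6 / 7.75, rel=1e-10)

    def test_zero_function_averages_to_zero(self, fig2d):
        ss = steady_state(build_pair_graph(fig2d))
        assert average_occupancy(ss, {v: 0 for v in "e s o so".split()}) == 0.0

    def test_additivity_over_product_graphs(self, fig2d, fig2e):
        """<eta>_{G1xG2} = <eta>_{G1} + <eta>_{G2} (16-state check)."""
        g1, g2 = build_pair_graph(fig2d), build_pair_graph(fig2e)
        eta_prod = {(i, j): ETA_S[i] + ETA_S[j] for i in g1.vertices for j in g2.vertices}
        lhs = average_occupancy(steady_state(product_graph(g1, g2)), eta_prod)
        rhs = average_occupancy(steady_state(g1), ETA_S) + average_occupancy(
            steady_state(g2), ETA_S
        )
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_additivity_on_random_components(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            g1 = random_reversible_graph(rng, n_max=4)
            g2 = random_reversible_graph(rng, n_max=4)
            eta1 = {v: int(rng.integers(0, 3)) for v in g1.vertices}
            eta2 = {v: int(rng.integers(0, 3)) for v in g2.vertices}
            eta = {(i, j): eta1[i] + eta2[j] for i in g1.vertices for j in g2.vertices}
            lhs = average_occupancy(steady_state(product_graph(g1, g2)), eta)
            rhs = average_occupancy(steady_state(g1), eta1) + average_occupancy(
                steady_state(g2), eta2
            )
            assert lhs == pytest.approx(rhs, rel=1e-10, abs=1e-12)

    def test_missing_vertex_rejected(self, fig2d):
        ss = steady_state(build_pair_graph(fig2d))
        with pytest.raises(ValueError, match="so"):
            average_occupancy(ss, {"e": 0, "s": 1, "o": 0})


class TestMixtureFraction:
    @pytest.mark.parametrize(
        "l,f1,f2,expected", [(1.0, 0.2, 0.8, 0.2), (0.67, 0.2, 0.8, 0.398), (0.5, 0.3, 0.3, 0.3)]
    )
    def test_values(self, l, f1, f2, expected):
        assert mixture_fraction(l, f1, f2) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mixture_fraction(1.2, 0.5, 0.5)


class TestEquilibriumTypeFractions:
    PARAMS = EquilibriumLocusParams(K_S=1.5, K_O=0.75, omega=4.0, K_S_i=1.5, K_O_i=0.75)

    def test_matches_single_locus_closed_form(self):
        _, _, _, P4 = equilibrium_type_fractions(self.PARAMS)
        assert P4 == pytest.approx(6 / 7.75)

    @pytest.mark.parametrize("omega,cmp", [(4.0, 1), (0.25, -1)])
    def test_omega_orders_induced_vs_basal(self, omega, cmp):
        params = EquilibriumLocusParams(
            K_S=1.5, K_O=0.75, omega=omega, K_S_i=2.0, K_O_i=1.1
        )
        P1, P2, P3, P4 = equilibrium_type_fractions(params)
        assert np.sign(P4 - P1) == cmp and np.sign(P3 - P2) == cmp

    def test_independence_equalizes_induced_and_basal(self):
        params = EquilibriumLocusParams(
            K_S=1.5, K_O=0.75, omega=1.0, K_S_i=2.0, K_O_i=1.1
        )
        P1, P2, P3, P4 = equilibrium_type_fractions(params)
        assert P4 == pytest.approx(P1, rel=1e-12)
        assert P3 == pytest.approx(P2, rel=1e-12)

    def test_equals_scalable_mixture_route(self, fig3b):
        """Per-type closed forms equal the explicit Matrix-Tree computation,
        so mixtures never need the 4^N-state product graph."""
        from tfreciprocity import equilibrium_params_from_table
        from tfreciprocity.diversity import _type_fractions

        table = fig3b.type1
        params = equilibrium_params_from_table(
            table, sox2_induced_conc=2.0, oct4_induced_conc=0.5
        )
        closed = equilibrium_type_fractions(params)
        explicit = _type_fractions(table, 2.0, 0.5)
        assert closed == pytest.approx(explicit, rel=1e-10)


class TestDiversityGamma:
    def test_same_sign_cooperativity_stays_positive(self, fig3b):
        surf = diversity_surface(fig3b)
        assert surf.min() > 0

    def test_broken_detailed_balance_reaches_data_level(self, fig3c):
        surf = diversity_surface(fig3c)
        assert surf.min() <= -0.22

    def test_mixed_cooperativity_at_equilibrium_reaches_data_level(self, fig3d):
        surf = diversity_surface(fig3d)
        assert surf.min() <= -0.22

    def test_point_call_matches_surface(self, fig3c):
        res = diversity_gamma(fig3c, 2.0, 3.0)
        surf = diversity_surface(fig3c, [2.0], [3.0])
        assert res.gamma == pytest.approx(surf.gamma[0, 0], rel=1e-10)
        assert res.gamma == pytest.approx(
            (res.ratio_S - 1) * (res.ratio_O - 1), rel=1e-12
        )

    def test_sign_theorem_random_same_sign_mixtures(self):
        """Equilibrium mixtures with both omegas on the same side of 1 never
        produce negative reciprocity."""
        rng = np.random.default_rng(23)
        for trial in range(20):
            lo, hi = ((1.01, 8.0), (0.1, 0.99))[trial % 2]
            t1 = generate_locus_model(1000 + trial, equilibrium=True, omega_target=(lo, hi))
            t2 = generate_locus_model(2000 + trial, equilibrium=True, omega_target=(lo, hi))
            mix = GenomeMixture(type1=t1, type2=t2, l=float(rng.uniform(0, 1)))
            res = diversity_gamma(
                mix, float(10 ** rng.uniform(-1.5, 1.5)), float(10 ** rng.uniform(-1.5, 1.5))
            )
            assert res.gamma > -1e-12

    def test_json_round_trip(self, tmp_path, fig3d):
        path = tmp_path / "mixture.json"
        fig3d.to_json(path)
        back = GenomeMixture.from_json(path)
        assert back == fig3d


class TestSignTheoremScan:
    def test_randomized_equilibrium_single_locus_never_negative(self):
        """Closed-form scan: Gamma >= 0 at equilibrium, = 0 iff omega = 1."""
        rng = np.random.default_rng(99)
        n = 2000
        K_S = 10 ** rng.uniform(-2, 2, n)
        K_O = 10 ** rng.uniform(-2, 2, n)
        K_Si = 10 ** rng.uniform(-2, 2, n)
        K_Oi = 10 ** rng.uniform(-2, 2, n)
        omega = 10 ** rng.uniform(-2, 2, n)
        P1 = K_S / (1 + K_S)
        P2 = K_O / (1 + K_O)
        P3 = K_O * (1 + omega * K_Si) / (1 + K_Si + K_O * (1 + omega * K_Si))
        P4 = K_S * (1 + omega * K_Oi) / (1 + K_Oi + K_S * (1 + omega * K_Oi))
        gam = (P4 / P1 - 1) * (P3 / P2 - 1)
        assert (gam > -1e-14).all()
        # omega = 1 collapses Gamma to 0 exactly
        P3_ind = K_O * (1 + K_Si) / (1 + K_Si + K_O * (1 + K_Si))
        P4_ind = K_S * (1 + K_Oi) / (1 + K_Oi + K_S * (1 + K_Oi))
        gam0 = (P4_ind / P1 - 1) * (P3_ind / P2 - 1)
        assert np.abs(gam0).max() < 1e-12

    def test_omega_one_single_locus(self):
        assert single_locus_fraction(1.5, 0.75, 1.0) == pytest.approx(
            single_locus_fraction(1.5, 0.0, 1.0)
        )
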