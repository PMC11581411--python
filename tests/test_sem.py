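"""Identification layer: path tracing, d-separation, instrumental sets."""

import numpy as np
import pytest

from mvmrset import sem


def _fig_b_graph(alpha=0.3):
    """Two exposures, each with its own causal variant; variants in LD."""
    g = sem.CausalGraph()
    for n in ("E1", "E2"):
        g.add_node(n, role=sem.ROLE_INSTRUMENT)
    for n in ("X1", "X2"):
        g.add_node(n, role=sem.ROLE_EXPOSURE)
    g.add_node("Y", role=sem.ROLE_OUTCOME)
    g.add_bidirected("E1", "E2", alpha)
    g.add_edge("E1", "X1", 0.25)
    g.add_edge("E2", "X2", 0.2)
    g.add_edge("X1", "Y", 0.2)
    g.add_edge("X2", "Y", 0.6)
    return g


def _fig_c_graph(alpha=0.3):
    """One causal variant for two exposures; the second variant only in LD."""
    g = sem.CausalGraph()
    for n in ("E1", "E2", "X1", "X2", "Y"):
        g.add_node(n)
    g.add_bidirected("E1", "E2", alpha)
    g.add_edge("E1", "X1", 0.25)
    g.add_edge("E1", "X2", 0.2)
    g.add_edge("X1", "Y", 0.2)
    g.add_edge("X2", "Y", 0.6)
    return g


class TestImpliedCovariance:
    def test_no_edges_returns_error_covariance(self):
        s = sem.LinearSEM(C=np.zeros((3, 3)), Psi=np.eye(3), node_order=list("abc"))
        assert np.allclose(sem.implied_covariance(s), np.eye(3))

    def test_exact_k_sem_satisfies_identification_identity(self, exact_k_sem):
        Sigma = sem.implied_covariance(exact_k_sem)
        B = Sigma[:2, 2:4]
        ey = Sigma[:2, 4]
        assert np.allclose(B @ np.array([0.2, 0.6]), ey, atol=1e-14)

    def test_symmetric_and_psd(self, rng):
        _, lsem = sem.random_standardized_sem(rng, 7)
        S = sem.implied_covariance(lsem)
        assert np.allclose(S, S.T)
        assert np.linalg.eigvalsh(S).min() > -1e-10


class TestWrightPathSum:
    def test_single_mediated_path(self):
        g = sem.CausalGraph()
        for n in ("E", "X", "Y"):
            g.add_node(n)
        g.add_edge("E", "X", 0.8)
        g.add_edge("X", "Y", 0.3)
        assert sem.wright_path_sum(g, "E", "Y") == pytest.approx(0.24)

    def test_d_separated_nodes_sum_to_zero(self):
        g = sem.CausalGraph()
        for n in ("A", "B"):
            g.add_node(n)
        assert sem.wright_path_sum(g, "A", "B") == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_matrix_formula_on_random_sems(self, seed):
        """Path-tracing equals the SEM covariance formula entrywise."""
        g, lsem = sem.random_standardized_sem(np.random.default_rng(seed), 7)
        S = sem.implied_covariance(lsem)
        p = len(lsem.node_order)
        for a in range(p):
            for b in range(a + 1, p):
                w = sem.wright_path_sum(g, lsem.node_order[a], lsem.node_order[b])
                assert w == pytest.approx(S[a, b], abs=1e-10)

    def test_root_variance_correction_for_unstandardized_nodes(self):
        # common cause with variance 4: cov(X, Z) = a*b*Var(root)
        g = sem.CausalGraph()
        g.add_node("R", error_variance=4.0)
        g.add_node("X", error_variance=1.0)
        g.add_node("Z", error_variance=1.0)
        g.add_edge("R", "X", 0.5)
        g.add_edge("R", "Z", 0.25)
        expected = 0.5 * 0.25 * 4.0
        got = sem.wright_path_sum(g, "X", "Z", node_variances={"R": 4.0})
        assert got == pytest.approx(expected)
        S = sem.implied_covariance(g.to_sem())
        i, j = g.to_sem().index("X"), g.to_sem().index("Z")
        assert got == pytest.approx(S[i, j])

    def test_path_limit_fails_loudly(self):
        g = _fig_c_graph()
        with pytest.raises(sem.PathExplosionError):
            sem.wright_path_sum(g, "E1", "Y", max_paths=1)


class TestDSeparation:
    def test_direct_edge_is_connected(self):
        g = sem.CausalGraph().add_node("a").add_node("b")
        g.add_edge("a", "b", 0.5)
        assert not sem.d_separated(g, "a", "b")

    def test_collider_blocks(self):
        g = sem.CausalGraph()
        for n in ("a", "b", "v"):
            g.add_node(n)
        g.add_edge("a", "v", 0.5)
        g.add_edge("b", "v", 0.5)
        assert sem.d_separated(g, "a", "b")

    def test_unknown_node_rejected(self):
        g = sem.CausalGraph().add_node("a")
        with pytest.raises(sem.GraphInputError):
            sem.d_separated(g, "a", "nope")

    @pytest.mark.parametrize("seed", range(20))
    def test_symmetric_and_consistent_with_zero_covariance(self, seed):
        """Marginal d-separation <=> vanishing model covariance (generic)."""
        g, lsem = sem.random_standardized_sem(np.random.default_rng(seed), 6)
        S = sem.implied_covariance(lsem)
        names = lsem.node_order
        for a in range(6):
            for b in range(a + 1, 6):
                sep = sem.d_separated(g, names[a], names[b])
                assert sep == sem.d_separated(g, names[b], names[a])
                if sep:
                    assert abs(S[a, b]) < 1e-12
                else:
                    # random parameters make path cancellation negligible
                    assert abs(S[a, b]) > 1e-12


class TestInstrumentalSet:
    def test_correlated_variant_pair_is_an_instrumental_set(self):
        res = sem.check_instrumental_set(
            _fig_b_graph(), ["E1", "E2"], ["X1", "X2"], "Y"
        )
        assert isinstance(res, sem.PathCertificate)
        assert len(res.pairing) == 2
        assert {e for e, _, _ in res.pairing} == {"E1", "E2"}
        assert {x for _, x, _ in res.pairing} == {"X1", "X2"}

    def test_single_causal_variant_refused(self):
        res = sem.check_instrumental_set(
            _fig_c_graph(), ["E1", "E2"], ["X1", "X2"], "Y"
        )
        assert isinstance(res, sem.Refusal)
        assert res.condition == 3

    def test_classical_single_instrument_diagram(self):
        g = sem.CausalGraph()
        for n in ("E", "X", "Y"):
            g.add_node(n)
        g.add_edge("E", "X", 0.8)
        g.add_edge("X", "Y", 0.3)
        res = sem.check_instrumental_set(g, ["E"], ["X"], "Y")
        assert isinstance(res, sem.PathCertificate)
        assert res.pairing[0][2] == ("E", "X", "Y")

    def test_size_mismatch_rejected(self):
        with pytest.raises(sem.GraphInputError):
            sem.check_instrumental_set(_fig_b_graph(), ["E1"], ["X1", "X2"], "Y")

    def test_exposure_confounding_does_not_break_identification(self):
        # latent confounding between exposures and outcome is allowed
        g = _fig_b_graph()
        g2 = sem.CausalGraph()
        for n in g.nodes:
            g2.add_node(n)
        for (s, d), v in g.directed_edges.items():
            g2.add_edge(s, d, v)
        for (a, b), v in g.bidirected_edges.items():
            g2.add_bidirected(a, b, v)
        g2.add_bidirected("X1", "Y", 0.2)
        res = sem.check_instrumental_set(g2, ["E1", "E2"], ["X1", "X2"], "Y")
        assert isinstance(res, sem.PathCertificate)

    def test_certified_sets_identify_effects_exactly(self):
        """With a certificate, solving the linear system recovers the edges."""
        for seed in range(10):
            r = np.random.default_rng(seed)
            alpha = r.uniform(-0.6, 0.6)
            A = r.uniform(0.1, 0.3, (2, 2))
            c = r.uniform(-0.7, 0.7, 2)
            lsem = sem.build_mvmr_sem([[1, alpha], [alpha, 1]], A, c)
            S = sem.implied_covariance(lsem)
            got = sem.identify_effects(S[:2, 2:4], S[:2, 4])
            assert np.allclose(got, c, atol=1e-12)


class TestIdentifyEffects:
    def test_zero_outcome_covariance_gives_zero_effects(self):
        c = sem.identify_effects(np.array([[0.3, 0.1], [0.1, 0.4]]), np.zeros(2))
        assert np.allclose(c, 0.0)

    def test_rank_deficiency_refused(self):
        B = np.array([[0.3, 0.6], [0.15, 0.3]])  # proportional columns
        with pytest.raises(sem.UnderdeterminedError):
            sem.identify_effects(B, np.array([0.1, 0.05]))

    def test_overdetermined_system_matches_causal_subsystem(self):
        """Extra LD-only instruments leave the identified effects unchanged."""
        rng = np.random.default_rng(7)
        L, K = 5, 2
        ld = 0.4 ** np.abs(np.subtract.outer(np.arange(L), np.arange(L)))
        A = np.zeros((L, K))
        A[:K, :] = [[0.3, 0.12], [0.1, 0.28]]  # only the first two are causal
        c = np.array([0.2, 0.6])
        lsem = sem.build_mvmr_sem(ld, A, c)
        S = sem.implied_covariance(lsem)
        full = sem.identify_effects(S[:L, L : L + K], S[:L, L + K])
        sub = sem.identify_effects(S[:K, L : L + K], S[:K, L + K])
        assert np.allclose(full, c, atol=1e-12)
        assert np.allclose(sub, c, atol=1e-12)


class TestSerialization:
    def test_edgelist_round_trip(self):
        g = _fig_b_graph()
        back = sem.CausalGraph.from_edgelist(g.to_edgelist())
        assert back.directed_edges == g.directed_edges
        assert back.bidirected_edges == g.bidirected_edges
        assert back.nodes == g.nodes

    def test_cycle_rejected(self):
        g = sem.CausalGraph().add_node("a").add_node("b")
        g.add_edge("a", "b", 1.0)
        g.add_edge("b", "a", 1.0)
        with pytest.raises(sem.GraphInputError):
            g.to_sem()
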