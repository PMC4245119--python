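"""Interaction strengths, PSN construction, centralities vs brute-force
oracles, clique-percolation communities, persistence, allosteric paths."""
import numpy as np
import networkx as nx
import pytest

import psnkit as pk
from psnkit.network import (NetworkError, PSNGraph, edge_persistence)
from psnkit.synthetic import model_from_ca

import oracles


def chain_psn(corrs):
    """Path graph a-b-c-... with |C| values per edge."""
    g = nx.Graph()
    names = [chr(97 + i) for i in range(len(corrs) + 1)]
    for i, c in enumerate(corrs):
        g.add_edge(names[i], names[i + 1], C=c, w=float(-np.log(abs(c))))
    return PSNGraph(graph=g, keys=names, i_min=3.0)


class TestInteractionStrength:
    def test_distant_residues_zero(self):
        model = model_from_ca(
            np.array([[0.0, 0, 0], [3.8, 0, 0], [30.0, 30, 0],
                      [33.8, 30, 0]]), "AAAA")
        i_mat, _ = pk.interaction_strength_matrix(model)
        assert i_mat[0, 2] == 0.0 and i_mat[0, 3] == 0.0

    def test_hand_counted_contacts_with_custom_normalization(self):
        """4 atom-pair contacts with N_i = N_j = 16 give I = 25 %."""
        # residues 1 and 3 (|i-j| = 2) placed so that exactly the four
        # CA/CB pair combinations are within 4.5 A
        ca = np.array([[0.0, 0, 0], [3.8, 0, 0], [0.0, 30, 0],
                       [3.8, 30, 0]])
        model = model_from_ca(ca, "AAAA")
        coords = model.coords.copy()
        atoms_3 = model.atoms_of_group(2)
        coords[atoms_3] = coords[model.atoms_of_group(0)] \
            + np.array([0.0, 4.0, 0.0])
        model = model_from_ca(ca, "AAAA")
        model.coords[:] = coords
        i_mat, _ = pk.interaction_strength_matrix(
            model, normalization={"ALA": 16.0})
        d = np.sqrt(((model.coords[model.atoms_of_group(0)][:, None]
                      - model.coords[atoms_3][None]) ** 2).sum(2))
        n_pairs = int((d <= 4.5).sum())
        assert i_mat[0, 2] == pytest.approx(100.0 * n_pairs / 16.0)

    def test_symmetry_and_zero_diagonal(self, two_domain50):
        i_mat, _ = pk.interaction_strength_matrix(two_domain50)
        assert np.allclose(i_mat, i_mat.T)
        assert np.all(np.diag(i_mat) == 0)

    def test_sequence_neighbors_excluded(self, helix10):
        i_mat, _ = pk.interaction_strength_matrix(helix10)
        for i in range(9):
            assert i_mat[i, i + 1] == 0.0


class TestBuildPsn:
    def test_weight_closed_forms(self):
        i_mat = np.array([[0.0, 10, 10], [10, 0, 10], [10, 10, 0]])
        c = np.array([[1.0, 1.0, 0.5], [1.0, 1.0, 0.3], [0.5, 0.3, 1.0]])
        psn = pk.build_psn(i_mat, c, ["a", "b", "c"])
        assert psn.graph["a"]["b"]["w"] == pytest.approx(0.0)
        assert psn.graph["a"]["c"]["w"] == pytest.approx(np.log(2))

    def test_cutoff_is_strict(self):
        c = np.eye(2)
        psn = pk.build_psn(np.array([[0.0, 2.9], [2.9, 0]]), c, ["a", "b"])
        assert psn.graph.number_of_edges() == 0
        psn = pk.build_psn(np.array([[0.0, 3.1], [3.1, 0]]), c, ["a", "b"])
        assert psn.graph.number_of_edges() == 1

    def test_dimension_mismatch_error(self):
        with pytest.raises(NetworkError):
            pk.build_psn(np.zeros((3, 3)), np.eye(4), ["a", "b", "c"])


class TestDegreeHubs:
    def test_path_graph(self):
        psn = PSNGraph.from_networkx(nx.path_graph(3))
        prof = pk.degree_and_hubs(psn)
        assert prof.degree.tolist() == [1, 2, 1]
        assert not prof.hub.any()

    def test_star_center_is_hub_at_four(self):
        prof = pk.degree_and_hubs(nx.star_graph(4))
        assert prof.degree[0] == 4 and prof.hub[0]
        assert not prof.hub[1:].any()

    def test_edgeless(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        prof = pk.degree_and_hubs(g)
        assert np.all(prof.degree == 0)


class TestCentrality:
    def test_complete_graph_closeness_one(self):
        clo, iso = pk.closeness_profile(nx.complete_graph(4))
        assert np.allclose(clo, 1.0)

    def test_path_graph_closeness(self):
        clo, _ = pk.closeness_profile(nx.path_graph(3))
        assert np.allclose(clo, [2 / 3, 1.0, 2 / 3])

    def test_path_graph_betweenness(self):
        bc = pk.betweenness_profile(nx.path_graph(3))
        assert np.allclose(bc, [0, 1, 0])

    def test_star_betweenness(self):
        bc = pk.betweenness_profile(nx.star_graph(4))
        assert bc[0] == pytest.approx(1.0)
        assert np.allclose(bc[1:], 0)

    def test_isolated_node_flagged(self):
        g = nx.path_graph(3)
        g.add_node(99)
        clo, iso = pk.closeness_profile(g)
        assert clo[3] == 0.0 and iso[3]

    def test_negative_weight_error(self):
        g = nx.path_graph(3)
        g[0][1]["w"] = -0.5
        with pytest.raises(NetworkError):
            pk.betweenness_profile(PSNGraph.from_networkx(g))

    def test_matches_oracle_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for trial in range(20):
            g = oracles.random_weighted_graph(rng, int(rng.integers(4, 11)))
            psn = PSNGraph.from_networkx(g)
            clo, _ = pk.closeness_profile(psn)
            bc = pk.betweenness_profile(psn)
            assert np.abs(clo - oracles.brute_closeness(
                g, psn.keys)).max() < 1e-9
            assert np.abs(bc - oracles.brute_betweenness(
                g, psn.keys)).max() < 1e-9

    def test_betweenness_invariant_under_relabeling(self):
        rng = np.random.default_rng(8)
        g = oracles.random_weighted_graph(rng, 9)
        perm = rng.permutation(9)
        relabeled = nx.relabel_nodes(g, {i: f"n{perm[i]}" for i in g.nodes})
        bc = pk.betweenness_profile(PSNGraph.from_networkx(g))
        psn2 = PSNGraph.from_networkx(relabeled)
        bc2 = pk.betweenness_profile(psn2)
        for i in range(9):
            j = psn2.keys.index(f"n{perm[i]}")
            assert bc2[j] == pytest.approx(bc[i], abs=1e-12)
        assert bc.min() >= 0 and bc.max() <= 1 + 1e-12


class TestCliquePercolation:
    def test_two_triangles_sharing_edge_merge(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (1, 3), (2, 3)])
        comms = pk.cpm_communities(g, k=3)
        assert len(comms) == 1
        assert comms[0].members == frozenset({0, 1, 2, 3})

    def test_two_triangles_sharing_node_stay_separate(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (2, 3), (3, 4), (2, 4)])
        comms = pk.cpm_communities(g, k=3)
        assert len(comms) == 2

    def test_k_larger_than_max_clique_empty(self):
        assert pk.cpm_communities(nx.path_graph(5), k=3) == []

    def test_k_below_three_error(self):
        with pytest.raises(NetworkError):
            pk.cpm_communities(nx.complete_graph(4), k=2)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for trial in range(20):
            g = nx.erdos_renyi_graph(int(rng.integers(5, 13)), 0.5,
                                     seed=int(rng.integers(0, 2 ** 31)))
            got = {c.members for c in pk.cpm_communities(g, k=3)}
            assert got == oracles.brute_cpm(g, 3)

    def test_fixed_point_on_induced_subgraph(self):
        g = nx.erdos_renyi_graph(12, 0.5, seed=11)
        for comm in pk.cpm_communities(g, k=3):
            sub = g.subgraph(comm.members)
            again = pk.cpm_communities(sub, k=3)
            assert any(c.members == comm.members for c in again)

    def test_edge_monotonicity_in_i_min(self, two_domain50):
        i_mat, keys = pk.interaction_strength_matrix(two_domain50)
        c = np.eye(50)
        low = pk.build_psn(i_mat, c, keys, i_min=3.0)
        high = pk.build_psn(i_mat, c, keys, i_min=6.0)
        assert set(high.graph.edges) <= set(low.graph.edges)
        high_nodes = set().union(*(
            co.members for co in pk.cpm_communities(high, 3)), frozenset())
        low_nodes = set().union(*(
            co.members for co in pk.cpm_communities(low, 3)), frozenset())
        assert high_nodes <= low_nodes


class TestPersistence:
    def triangle_graph(self, present=True):
        g = nx.Graph()
        g.add_nodes_from(range(6))
        if present:
            g.add_edges_from([(0, 1), (1, 2), (0, 2)])
        g.add_edges_from([(3, 4), (4, 5), (3, 5)])
        return g

    def test_always_present_community_is_stable(self):
        graphs = [self.triangle_graph() for _ in range(10)]
        comms = pk.community_persistence(graphs)
        assert all(c.persistence == 1.0 and c.stable for c in comms)

    def test_six_of_ten_is_not_stable(self):
        graphs = [self.triangle_graph(present=i < 6) for i in range(10)]
        comms = pk.community_persistence(graphs)
        flicker = [c for c in comms if c.members == frozenset({0, 1, 2})]
        assert flicker[0].persistence == pytest.approx(0.6)
        assert not flicker[0].stable
        steady = [c for c in comms if c.members == frozenset({3, 4, 5})]
        assert steady[0].stable

    def test_node_set_mismatch_error(self):
        g1, g2 = nx.complete_graph(4), nx.complete_graph(5)
        with pytest.raises(NetworkError):
            pk.community_persistence([g1, g2])

    def test_edge_persistence_fractions(self):
        graphs = [self.triangle_graph(present=i < 6) for i in range(10)]
        edges = edge_persistence(graphs)
        assert edges[("0", "1")]["persistence"] == pytest.approx(0.6)
        assert not edges[("0", "1")]["stable"]
        assert edges[("3", "4")]["stable"]


class TestPaths:
    def test_chain_closed_form(self):
        psn = chain_psn([0.8, 0.8, 0.8])
        path = pk.shortest_allosteric_path(psn, "a", "d")
        assert path.nodes == ("a", "b", "c", "d")
        assert path.length == pytest.approx(3 * -np.log(0.8))

    def test_low_correlation_shortcut_excluded(self):
        psn = chain_psn([0.8, 0.8, 0.8])
        psn.graph.add_edge("a", "d", C=0.3, w=float(-np.log(0.3)))
        path = pk.shortest_allosteric_path(psn, "a", "d",
                                           corr_min=0.5, corr_max=1.0)
        assert path.nodes == ("a", "b", "c", "d")

    def test_disconnected_under_filter(self):
        psn = chain_psn([0.8, 0.2, 0.8])
        path = pk.shortest_allosteric_path(psn, "a", "d")
        assert not path.connected and "correlation filter" in path.reason

    def test_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            g = oracles.random_weighted_graph(rng, 9, p=0.45)
            for _, _, data in g.edges(data=True):
                data["C"] = 0.9
            if not nx.has_path(g, 0, 8):
                continue
            psn = PSNGraph.from_networkx(g)
            best = pk.shortest_allosteric_path(psn, 0, 8)
            expect, _ = oracles._all_shortest_paths(g, 0, 8)
            assert best.length == pytest.approx(expect, abs=1e-12)

    def test_suboptimal_zero_tolerance_is_optimum(self):
        psn = chain_psn([0.8, 0.8, 0.8])
        psn.graph.add_edge("a", "c", C=0.8, w=float(-np.log(0.8)))
        paths = pk.suboptimal_paths(psn, "a", "d", tolerance=0.0)
        assert len(paths) == 1 and paths[0].nodes == ("a", "c", "d")

    def test_suboptimal_large_tolerance_enumerates_all(self):
        rng = np.random.default_rng(10)
        g = oracles.random_weighted_graph(rng, 6, p=0.6)
        for _, _, data in g.edges(data=True):
            data["C"] = 0.9
        if not nx.has_path(g, 0, 5):
            pytest.skip("disconnected draw")
        psn = PSNGraph.from_networkx(g)
        got = pk.suboptimal_paths(psn, 0, 5, tolerance=1e6)
        expect = oracles.brute_suboptimal(g, 0, 5, 1e6)
        assert len(got) == len(expect)
        lengths = [p.length for p in got]
        assert lengths == sorted(lengths)
        assert lengths[0] == pytest.approx(expect[0][0])

    def test_source_equals_target_error(self):
        psn = chain_psn([0.8])
        with pytest.raises(NetworkError):
            pk.shortest_allosteric_path(psn, "a", "a")
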