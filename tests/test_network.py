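import networkx as nx
import numpy as np
import pytest

from allonet.coupling import CouplingMatrix
from allonet.errors import GraphError, InputError
from allonet.network import (
    CommunityPartition,
    ResidueGraph,
    all_pairs_shortest_paths,
    betweenness,
    build_contact_graph,
    community_cliques,
    girvan_newman,
    load_contact_normalization,
    persistent_communities,
)
from allonet.synthetic import EnsembleSpec, synth_ensemble

from conftest import graph_from_edges, make_bead_structure
from oracles import (
    betweenness_enumeration_oracle,
    dijkstra_oracle,
    random_weighted_graph,
)


def coupling_for(structure, r=0.5):
    n = structure.n_residues
    rm = np.full((n, n), r)
    np.fill_diagonal(rm, 0.0)
    w = -np.log(np.maximum(rm, 1e-300))
    np.fill_diagonal(w, 0.0)
    return CouplingMatrix(r_mi=rm, w=w,
                          residue_numbers=structure.residue_numbers,
                          flagged=np.zeros((n, n), dtype=bool))


class TestContactGraph:
    def test_strength_arithmetic(self):
        # n_ij = 3 contacts, N_i = N_j = 60 -> I = 100*3/60 = 5.0
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        s = make_bead_structure(coords)
        coup = coupling_for(s)
        g = build_contact_graph(s, coords, coup, I_min=0.0,
                                normalization={"ALA": 60.0})
        # single-bead residues give n_ij = 1 -> I = 100/60
        assert g.g.edges[0, 1]["strength"] == pytest.approx(100.0 / 60.0)
        # the printed arithmetic case
        assert 100.0 * 3 / np.sqrt(60.0 * 60.0) == pytest.approx(5.0)

    def test_i_min_above_all_strengths_gives_edgeless_graph(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0], [6.0, 0, 0]])
        s = make_bead_structure(coords)
        g = build_contact_graph(s, coords, coupling_for(s), I_min=99.0,
                                normalization={"ALA": 10.0})
        assert g.g.number_of_edges() == 0
        assert g.n_nodes == 3

    def test_missing_residue_type_falls_back_to_table_mean(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        s = make_bead_structure(coords, names=["ALA", "XXX"])
        with pytest.warns(UserWarning, match="XXX"):
            g = build_contact_graph(s, coords, coupling_for(s), I_min=0.0,
                                    normalization={"ALA": 4.0})
        assert g.g.edges[0, 1]["strength"] == pytest.approx(100.0 / 4.0)

    def test_infinite_w_edge_excluded(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        s = make_bead_structure(coords)
        coup = coupling_for(s)
        coup.w[0, 1] = coup.w[1, 0] = np.inf
        g = build_contact_graph(s, coords, coup, I_min=0.0,
                                normalization={"ALA": 1.0})
        assert g.g.number_of_edges() == 0

    def test_bundled_normalization_table(self):
        table = load_contact_normalization()
        assert len(table) == 20
        assert all(v > 0 for v in table.values())

    def test_negative_i_min_rejected(self):
        coords = np.zeros((2, 3))
        s = make_bead_structure(np.array([[0.0, 0, 0], [3.0, 0, 0]]))
        with pytest.raises(InputError):
            build_contact_graph(s, s.coords, coupling_for(s), I_min=-1.0)


class TestShortestPaths:
    def test_single_edge(self):
        g = graph_from_edges(2, {(0, 1): 2.0})
        pm = all_pairs_shortest_paths(g)
        assert pm.dist[0, 1] == 2.0
        assert pm.counts[0, 1] == 1

    def test_triangle_relaxation(self):
        g = graph_from_edges(3, {(0, 1): 1.0, (1, 2): 1.0, (0, 2): 3.0})
        pm = all_pairs_shortest_paths(g)
        assert pm.dist[0, 2] == 2.0

    def test_disconnected_pair(self):
        g = graph_from_edges(4, {(0, 1): 1.0, (2, 3): 1.0})
        pm = all_pairs_shortest_paths(g)
        assert np.isinf(pm.dist[0, 2])
        assert pm.counts[0, 2] == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_distances_match_dijkstra_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        edges = random_weighted_graph(rng, n)
        pm = all_pairs_shortest_paths(graph_from_edges(n, edges))
        for s in range(n):
            expect = dijkstra_oracle(n, edges, s)
            assert np.allclose(pm.dist[s], expect, atol=1e-12)

    def test_zero_length_edges_rejected(self):
        g = graph_from_edges(2, {(0, 1): 0.0})
        with pytest.raises(GraphError):
            all_pairs_shortest_paths(g)

    def test_removing_edge_never_shortens_distances(self, rng):
        edges = random_weighted_graph(rng, 10)
        pm_full = all_pairs_shortest_paths(graph_from_edges(10, edges))
        key = sorted(edges)[0]
        reduced = {k: v for k, v in edges.items() if k != key}
        pm_red = all_pairs_shortest_paths(graph_from_edges(10, reduced))
        assert np.all(pm_red.dist >= pm_full.dist - 1e-12)


class TestBetweenness:
    def test_three_node_path(self):
        g = graph_from_edges(3, {(0, 1): 1.0, (1, 2): 1.0})
        cent = betweenness(g)
        assert cent.normalized[1] == 1.0
        assert cent.normalized[0] == cent.normalized[2] == 0.0

    def test_star_center(self):
        edges = {(0, k): 1.0 for k in range(1, 6)}
        cent = betweenness(graph_from_edges(6, edges))
        assert cent.normalized[0] == 1.0
        assert np.all(cent.normalized[1:] == 0.0)

    def test_degree_one_nodes_have_zero(self, rng):
        edges = random_weighted_graph(rng, 9)
        g = graph_from_edges(9, edges)
        cent = betweenness(g)
        for node in g.g.nodes:
            if g.g.degree(node) == 1:
                assert cent.raw[node] == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(5, 11))
        edges = random_weighted_graph(rng, n)
        cent = betweenness(graph_from_edges(n, edges))
        expect = betweenness_enumeration_oracle(n, edges)
        assert np.allclose(cent.raw, expect, atol=1e-12)

    def test_matches_networkx_cross_check(self, rng):
        edges = random_weighted_graph(rng, 12)
        g = graph_from_edges(12, edges)
        cent = betweenness(g)
        expect = nx.betweenness_centrality(g.g, weight="length", normalized=True)
        assert np.allclose(cent.normalized, [expect[i] for i in range(12)],
                           atol=1e-10)


def two_cliques_graph():
    g = nx.Graph()
    for base in (0, 5):
        for i in range(5):
            for j in range(i + 1, 5):
                g.add_edge(base + i, base + j, length=1.0, strength=100.0)
    g.add_edge(4, 5, length=1.0, strength=100.0)
    return ResidueGraph(g=g)


class TestGirvanNewman:
    def test_single_clique_is_one_community(self):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 1.0, "length")
        part = girvan_newman(ResidueGraph(g=g))
        assert len(part.communities) == 1
        assert part.modularity == pytest.approx(0.0, abs=1e-12)

    def test_two_cliques_with_bridge(self):
        part = girvan_newman(two_cliques_graph())
        assert sorted(sorted(c) for c in part.communities) == [
            [0, 1, 2, 3, 4], [5, 6, 7, 8, 9]
        ]
        # hand formula: m = 21, Q = 2 * (10/21 - (21/42)^2)
        assert part.modularity == pytest.approx(2 * (10 / 21 - 0.25), abs=1e-10)

    def test_modularity_beats_trivial_partition(self, rng):
        from oracles import random_weighted_graph

        edges = random_weighted_graph(rng, 12)
        part = girvan_newman(graph_from_edges(12, edges))
        assert part.modularity >= 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_two_block_ensemble_recovered(self, seed):
        ens, truth = synth_ensemble(
            EnsembleSpec(seed=seed, n_frames=200, blocks=[(0, 15), (15, 30)],
                         bridges=[(14, 15)])
        )
        from allonet.coupling import coupling_matrix, pmi_profile

        pmi = pmi_profile(ens, np.zeros(30))
        coup = coupling_matrix(ens, pmi)
        g = build_contact_graph(ens.structure, ens.frames.mean(axis=0), coup)
        part = girvan_newman(g)
        got = sorted(sorted(c) for c in part.communities)
        assert got == [list(range(1, 16)), list(range(16, 31))]

    def test_community_cliques_postprocessor(self):
        g = two_cliques_graph()
        part = girvan_newman(g)
        cliques = community_cliques(g, part)
        assert [0, 1, 2, 3, 4] in cliques
        assert [5, 6, 7, 8, 9] in cliques


class TestPersistence:
    def _partition(self, *sets):
        return CommunityPartition(
            communities=[frozenset(s) for s in sets], modularity=0.3
        )

    def _frames(self, n_present, n_total=10):
        a, b = set(range(10)), set(range(10, 20))
        frames = []
        for k in range(n_total):
            if k < n_present:
                frames.append(self._partition(a, b))
            else:
                frames.append(self._partition(set(range(5)), set(range(5, 10)), b))
        return frames

    def test_community_in_8_of_10_frames_reported(self):
        out = persistent_communities(self._frames(8), persistence=0.75)
        reported = [p.communities[0] for p in out]
        assert frozenset(range(10)) in reported
        frac = [p.persistence for p in out if p.communities[0] == frozenset(range(10))]
        assert frac == [0.8]

    def test_community_in_7_of_10_frames_dropped(self):
        out = persistent_communities(self._frames(7), persistence=0.75)
        reported = [p.communities[0] for p in out]
        assert frozenset(range(10)) not in reported

    def test_stable_community_full_persistence(self):
        out = persistent_communities(self._frames(8), persistence=0.75)
        by_set = {p.communities[0]: p.persistence for p in out}
        assert by_set[frozenset(range(10, 20))] == 1.0

    def test_jaccard_matching_tolerates_small_changes(self):
        a = frozenset(range(10))
        a_jittered = frozenset(list(range(9)) + [99])  # jaccard 9/11 ~ 0.82
        frames = [self._partition(a, set(range(10, 20)))] * 8
        frames += [self._partition(a_jittered, set(range(10, 20)))] * 2
        out = persistent_communities(frames, persistence=0.75)
        assert frozenset(range(10)) in [p.communities[0] for p in out]

    def test_needs_two_frames(self):
        with pytest.raises(InputError):
            persistent_communities([self._partition({1, 2})])
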