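import numpy as np
import pytest

from allonet.coupling import CouplingMatrix, PMIProfile, coupling_matrix, pmi_profile
from allonet.errors import GraphError, InputError
from allonet.network import (
    CommunityPartition,
    all_pairs_shortest_paths,
    build_contact_graph,
    girvan_newman,
)
from allonet.pathways import (
    Path,
    _mean_abs_diff_to_all,
    annotate_hops,
    communication_propensity,
    path_ensemble,
    tune_weights,
)
from allonet.synthetic import EnsembleSpec, synth_ensemble

from conftest import make_bead_ensemble


def uniform_pmi(ens, values=None):
    n = ens.structure.n_residues
    per_frame = np.zeros((ens.frame_count, n)) if values is None else values
    return PMIProfile(mean=per_frame.mean(axis=0), per_frame=per_frame,
                      residue_numbers=ens.structure.residue_numbers,
                      threshold=5.0, aggregate="mean")


def full_coupling(structure, r=0.5):
    n = structure.n_residues
    rm = np.full((n, n), r)
    np.fill_diagonal(rm, 0.0)
    w = -np.log(rm + np.eye(n))
    return CouplingMatrix(r_mi=rm, w=w,
                          residue_numbers=structure.residue_numbers,
                          flagged=np.zeros((n, n), dtype=bool))


class TestCommunicationPropensity:
    def test_rigid_ensemble_gives_zero(self):
        frame = np.random.default_rng(0).uniform(0, 20, (6, 3))
        ens = make_bead_ensemble(np.stack([frame] * 10))
        cp = communication_propensity(ens, uniform_pmi(ens))
        assert np.allclose(cp.cp, 0.0, atol=1e-12)

    def test_w2_zero_raw_mode_equals_distance_variance(self):
        rng = np.random.default_rng(1)
        frames = rng.uniform(0, 20, (40, 5, 3))
        ens = make_bead_ensemble(frames)
        w1 = 0.7
        cp = communication_propensity(ens, uniform_pmi(ens), w1=w1, w2=0.0,
                                      normalize=False)
        # oracle: per frame mean CA distance of each residue to all others
        d = np.zeros((40, 5))
        for f in range(40):
            dm = np.linalg.norm(frames[f][:, None] - frames[f][None, :], axis=2)
            d[f] = dm.sum(axis=1) / 4
        expect = 3.0 * w1 * d.var(axis=0)
        assert np.allclose(cp.cp, expect, atol=1e-10)

    def test_frame_order_invariance(self):
        rng = np.random.default_rng(2)
        frames = rng.uniform(0, 15, (30, 4, 3))
        pmi_vals = rng.uniform(0, 5, (30, 4))
        a = communication_propensity(make_bead_ensemble(frames),
                                     uniform_pmi(make_bead_ensemble(frames), pmi_vals))
        perm = rng.permutation(30)
        ens_p = make_bead_ensemble(frames[perm])
        b = communication_propensity(ens_p, uniform_pmi(ens_p, pmi_vals[perm]))
        assert np.allclose(a.cp, b.cp, atol=1e-10)

    def test_scales_linearly_in_w1(self):
        rng = np.random.default_rng(3)
        frames = rng.uniform(0, 15, (25, 4, 3))
        ens = make_bead_ensemble(frames)
        a = communication_propensity(ens, uniform_pmi(ens), w1=0.5, w2=0.0)
        b = communication_propensity(ens, uniform_pmi(ens), w1=1.0, w2=0.0)
        assert np.allclose(b.cp, 2 * a.cp, atol=1e-10)

    def test_mean_abs_diff_matches_brute_force(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(-3, 3, (7, 9))
        got = _mean_abs_diff_to_all(x)
        for f in range(7):
            for i in range(9):
                expect = np.abs(x[f, i] - np.delete(x[f], i)).mean()
                assert got[f, i] == pytest.approx(expect, abs=1e-12)

    def test_needs_two_frames(self):
        ens = make_bead_ensemble(np.zeros((1, 4, 3)))
        with pytest.raises(InputError):
            communication_propensity(ens, uniform_pmi(ens))


class TestTuneWeights:
    def test_grid_of_one_returns_that_point(self):
        ens, _ = synth_ensemble(EnsembleSpec(seed=0, n_frames=60))
        pmi = uniform_pmi(ens)
        coup = coupling_matrix(ens, pmi)
        assert tune_weights(ens, pmi, coup, grid=[(0.3, 0.7)]) == (0.3, 0.7)

    def test_distance_only_structure_selects_w1(self):
        # block structure lives in the distance channel; the pMI channel
        # is pure noise -> w1 = 1.0 maximizes modularity
        ens, _ = synth_ensemble(EnsembleSpec(seed=1, n_frames=150))
        rng = np.random.default_rng(5)
        noise_pmi = uniform_pmi(ens, rng.uniform(0, 3, (150, 60)))
        coup = coupling_matrix(ens, noise_pmi)
        w1, w2 = tune_weights(ens, noise_pmi, coup)
        assert w1 == 1.0
        assert w2 == 0.0

    def test_deterministic(self):
        ens, _ = synth_ensemble(EnsembleSpec(seed=2, n_frames=80))
        pmi = uniform_pmi(ens)
        coup = coupling_matrix(ens, pmi)
        assert tune_weights(ens, pmi, coup) == tune_weights(ens, pmi, coup)


class TestPathEnsemble:
    def _line_ensemble(self, n_frames=4):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0], [6.0, 0, 0], [9.0, 0, 0]])
        return make_bead_ensemble(np.stack([coords] * n_frames))

    def test_identical_frames_single_path_full_occupancy(self):
        ens = self._line_ensemble()
        pe = path_ensemble(ens, full_coupling(ens.structure), source=1, sink=4,
                           I_min=0.0, normalization={"ALA": 1.0})
        assert len(pe.paths) == 1
        assert pe.paths[0].occupancy == 1.0
        assert pe.paths[0].residues == (1, 2, 3, 4)

    def test_alternating_topologies_split_occupancy(self):
        # diamond: 1 -> (2 or 3) -> 4; frames alternate which arm is in
        # contact range
        near, far = 3.0, 50.0
        frame_a = np.array([[0.0, 0, 0], [near, 0, 0], [0.0, far, 0], [near + 3, 0, 0]])
        frame_b = np.array([[0.0, 0, 0], [far, far, 0], [3.0, 0.5, 0], [3.0, 3.5, 0]])
        frames = np.stack([frame_a, frame_b] * 5)
        ens = make_bead_ensemble(frames)
        pe = path_ensemble(ens, full_coupling(ens.structure), source=1, sink=4,
                           I_min=0.0, normalization={"ALA": 1.0})
        occ = {p.residues: p.occupancy for p in pe.paths}
        assert occ[(1, 2, 4)] == 0.5
        assert occ[(1, 3, 4)] == 0.5

    def test_occupancies_sum_to_one(self):
        ens, truth = synth_ensemble(
            EnsembleSpec(seed=3, n_frames=100, corridor=True)
        )
        pmi = uniform_pmi(ens)
        coup = coupling_matrix(ens, pmi)
        pe = path_ensemble(ens, coup, source=truth["source_residue"],
                           sink=truth["sink_residue"])
        assert abs(sum(p.occupancy for p in pe.paths) - 1.0) < 1e-12

    def test_corridor_dominates_occupancy(self):
        # spec'd fixture conditions: 200 frames, one low-weight corridor
        ens, truth = synth_ensemble(
            EnsembleSpec(seed=4, n_frames=200, corridor=True)
        )
        coup = coupling_matrix(ens, uniform_pmi(ens))
        pe = path_ensemble(ens, coup, source=truth["source_residue"],
                           sink=truth["sink_residue"])
        assert pe.paths[0].residues == tuple(truth["corridor_residue_numbers"])
        assert pe.paths[0].occupancy >= 0.9

    def test_path_length_equals_path_matrix_distance(self):
        ens = self._line_ensemble()
        coup = full_coupling(ens.structure)
        pe = path_ensemble(ens, coup, source=1, sink=4, I_min=0.0,
                           normalization={"ALA": 1.0})
        g = build_contact_graph(ens.structure, ens.frames[0], coup, I_min=0.0,
                                normalization={"ALA": 1.0})
        pm = all_pairs_shortest_paths(g)
        assert pe.paths[0].length == pytest.approx(pm.dist[0, 3], abs=1e-12)

    def test_disconnected_majority_raises(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0], [50.0, 0, 0], [53.0, 0, 0]])
        ens = make_bead_ensemble(np.stack([coords] * 6))
        with pytest.raises(GraphError, match="disconnected"):
            path_ensemble(ens, full_coupling(ens.structure), source=1, sink=4,
                          I_min=0.0, normalization={"ALA": 1.0})

    def test_mean_mode_returns_boltzmann_weighted_routes(self):
        ens = self._line_ensemble()
        pe = path_ensemble(ens, full_coupling(ens.structure), source=1, sink=4,
                           I_min=0.0, normalization={"ALA": 1.0}, mode="mean",
                           k_paths=3)
        assert pe.paths[0].residues == (1, 2, 3, 4)
        assert abs(sum(p.occupancy for p in pe.paths) - 1.0) < 1e-12

    def test_invalid_endpoints_rejected(self):
        ens = self._line_ensemble()
        coup = full_coupling(ens.structure)
        with pytest.raises(InputError):
            path_ensemble(ens, coup, source=1, sink=1)
        with pytest.raises(InputError):
            path_ensemble(ens, coup, source=1, sink=99)


class TestHopAnnotation:
    def _partition(self, *sets):
        return CommunityPartition(
            communities=[frozenset(s) for s in sets], modularity=0.4
        )

    def test_path_within_one_community_has_no_hops(self):
        part = self._partition({1, 2, 3, 4}, {5, 6})
        p = annotate_hops(Path(residues=(1, 2, 3), occupancy=1.0, length=1.0), part)
        assert p.hops == []

    def test_path_crossing_three_communities_has_two_hops(self):
        part = self._partition({1, 2}, {3, 4}, {5, 6})
        p = annotate_hops(Path(residues=(1, 2, 3, 4, 5), occupancy=1.0, length=1.0),
                          part)
        assert len(p.hops) == 2
        assert (p.hops[0].from_residue, p.hops[0].to_residue) == (2, 3)
        assert (p.hops[1].from_residue, p.hops[1].to_residue) == (4, 5)

    def test_hop_reports_cp_values(self):
        rng = np.random.default_rng(6)
        frames = rng.uniform(0, 10, (20, 4, 3))
        ens = make_bead_ensemble(frames)
        cp = communication_propensity(ens, uniform_pmi(ens))
        part = self._partition({1, 2}, {3, 4})
        p = annotate_hops(Path(residues=(1, 2, 3), occupancy=1.0, length=1.0),
                          part, cp)
        assert p.hops[0].cp_from == pytest.approx(cp.cp[1])
        assert p.hops[0].cp_to == pytest.approx(cp.cp[2])

    def test_uncovered_residue_rejected(self):
        part = self._partition({1, 2})
        with pytest.raises(InputError):
            annotate_hops(Path(residues=(1, 9), occupancy=1.0, length=1.0), part)

    def test_planted_bridge_is_the_hop_on_fixture(self):
        ens, truth = synth_ensemble(EnsembleSpec(seed=7, n_frames=200, corridor=True))
        coup = coupling_matrix(ens, uniform_pmi(ens))
        g = build_contact_graph(ens.structure, ens.frames.mean(axis=0), coup)
        part = girvan_newman(g)
        pe = path_ensemble(ens, coup, source=truth["source_residue"],
                           sink=truth["sink_residue"])
        p = annotate_hops(pe.paths[0], part)
        hop_pairs = {(h.from_residue, h.to_residue) for h in p.hops}
        planted = {tuple(b) for b in truth["bridge_residue_numbers"]}
        assert hop_pairs == planted
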