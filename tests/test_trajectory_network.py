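"""RMSF, native contacts, generalized correlation, and communities."""

import numpy as np
import networkx as nx
import pytest

from domaincoupling import synthetic_data as sim
from domaincoupling import trajectory_network as net
from domaincoupling.types import TrajectoryEnsemble, ValidationError


def _random_rotation(seed):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _apply_rigid(traj, rot, shift):
    frames = traj.frames @ rot.T + shift
    return TrajectoryEnsemble(residue_ids=traj.residue_ids, frames=frames,
                              reference=traj.reference)


@pytest.fixture(scope="module")
def jitter_traj():
    spec = sim.TrajectorySimSpec(n_residues=40, n_frames=400, communities=(),
                                 inter_corr=0.0, fluctuation_sd=0.4, seed=31)
    return sim.simulate_trajectory(spec)


class TestRMSF:
    def test_static_frames_have_zero_rmsf(self, jitter_traj):
        static = TrajectoryEnsemble(
            residue_ids=jitter_traj.residue_ids,
            frames=np.repeat(jitter_traj.reference[None], 12, axis=0),
            reference=jitter_traj.reference)
        prof = net.rmsf(static)
        assert np.allclose(prof.rmsf, 0.0, atol=1e-10)

    def test_rigid_rotation_leaves_rmsf_unchanged(self, jitter_traj):
        prof = net.rmsf(jitter_traj)
        moved = _apply_rigid(jitter_traj, _random_rotation(3),
                             np.array([5.0, -2.0, 9.0]))
        prof2 = net.rmsf(moved)
        assert np.allclose(prof.rmsf, prof2.rmsf, atol=1e-8)

    def test_matches_brute_force_recount(self, jitter_traj):
        prof = net.rmsf(jitter_traj)
        aligned = net.superpose_frames(jitter_traj)
        mean = aligned.mean(axis=0)
        brute = np.array([
            np.sqrt(np.mean([np.sum((aligned[f, i] - mean[i]) ** 2)
                             for f in range(jitter_traj.n_frames)]))
            for i in range(jitter_traj.n_residues)])
        assert np.allclose(prof.rmsf, brute, atol=1e-12)

    def test_collinear_reference_rejected(self):
        ref = np.zeros((5, 3))
        ref[:, 0] = np.arange(5)
        traj = TrajectoryEnsemble(residue_ids=list(range(1, 6)),
                                  frames=np.repeat(ref[None], 12, axis=0),
                                  reference=ref)
        with pytest.raises(ValidationError, match="degenerate"):
            net.rmsf(traj)

    def test_too_few_frames_rejected(self, jitter_traj):
        short = TrajectoryEnsemble(residue_ids=jitter_traj.residue_ids,
                                   frames=jitter_traj.frames[:5],
                                   reference=jitter_traj.reference)
        with pytest.raises(ValidationError):
            net.rmsf(short)


class TestNativeContacts:
    def test_reference_frames_give_exact_q_one(self, jitter_traj):
        static = TrajectoryEnsemble(
            residue_ids=jitter_traj.residue_ids,
            frames=np.repeat(jitter_traj.reference[None], 3, axis=0),
            reference=jitter_traj.reference)
        nc = net.native_contacts(static)
        assert np.all(nc.q_per_frame == 1.0)

    def test_rigid_motion_invariance(self, jitter_traj):
        nc = net.native_contacts(jitter_traj)
        moved = _apply_rigid(jitter_traj, _random_rotation(7),
                             np.array([-3.0, 8.0, 1.0]))
        nc2 = net.native_contacts(moved)
        assert np.allclose(nc.q_per_frame, nc2.q_per_frame, atol=1e-12)

    def test_matches_brute_force_recount(self, jitter_traj):
        nc = net.native_contacts(jitter_traj)
        thresh = net.CONTACT_CUTOFF * (1 + net.CONTACT_TOLERANCE)
        for f in (0, 17, 199):
            hits = sum(
                np.linalg.norm(jitter_traj.frames[f, i]
                               - jitter_traj.frames[f, j]) <= thresh
                for i, j in nc.contacts)
            assert nc.q_per_frame[f] == pytest.approx(hits / len(nc.contacts))

    def test_planted_loss_of_half_the_subset(self):
        """Displacing partners of half the subset pairs halves subset Q."""
        base = sim.TrajectorySimSpec(n_residues=64, n_frames=100,
                                     communities=(), inter_corr=0.0,
                                     fluctuation_sd=0.3, seed=5)
        ref_traj = sim.simulate_trajectory(base)
        pairs = net.native_contact_pairs(ref_traj.reference)
        used, subset = set(), []
        for i, j in pairs:
            if i not in used and j not in used:
                subset.append((i, j))
                used.update((i, j))
            if len(subset) == 10:
                break
        subset = np.array(subset)
        lost = sim.ContactLoss(residues=tuple(int(j) for _, j in subset[:5]))
        traj = sim.simulate_trajectory(sim.TrajectorySimSpec(
            n_residues=64, n_frames=100, communities=(), inter_corr=0.0,
            fluctuation_sd=0.3, seed=5, contact_loss=lost))
        nc = net.native_contacts(traj, subset=subset)
        assert np.mean(nc.q_subset) == pytest.approx(0.50, abs=0.02)

    def test_empty_contact_set_suggests_larger_cutoff(self, jitter_traj):
        with pytest.raises(ValidationError, match="cutoff"):
            net.native_contacts(jitter_traj, cutoff=0.5)


class TestGeneralizedCorrelation:
    def test_identical_motion_saturates(self):
        spec = sim.TrajectorySimSpec(n_residues=4, n_frames=3000,
                                     communities=(), inter_corr=0.0,
                                     fluctuation_sd=0.5, seed=41)
        traj = sim.simulate_trajectory(spec)
        frames = traj.frames.copy()
        frames[:, 1] = frames[:, 0] + np.array([3.8, 0, 0])
        twin = TrajectoryEnsemble(residue_ids=traj.residue_ids, frames=frames,
                                  reference=traj.reference)
        c = net.generalized_correlation(twin, pairs=np.array([[0, 1]]),
                                        superpose=False)
        assert c.correlation[0, 1] >= 0.95

    def test_independent_residues_stay_low(self):
        """Null level of the k-NN estimator on independent residues.

        Because r_MI = sqrt(1 - exp(-2I/3)) stretches tiny I values, the
        finite-sample null sits near 0.06 with per-pair scatter of a few
        hundredths; the median over pairs must stay below 0.1.
        """
        spec = sim.TrajectorySimSpec(n_residues=8, n_frames=5000,
                                     communities=(), inter_corr=0.0,
                                     fluctuation_sd=0.5, seed=42)
        traj = sim.simulate_trajectory(spec)
        c = net.generalized_correlation(traj, superpose=False)
        off = c.correlation[np.triu_indices(8, 1)]
        assert np.median(off) < 0.1
        assert np.max(off) < 0.15

    def test_gaussian_closed_form_rho_08(self):
        """r_MI equals the per-coordinate correlation for joint Gaussians."""
        spec = sim.TrajectorySimSpec(n_residues=2, n_frames=5000,
                                     communities=((0,), (1,)),
                                     intra_corr=0.9, inter_corr=0.8,
                                     fluctuation_sd=0.5, seed=43)
        traj = sim.simulate_trajectory(spec)
        c = net.generalized_correlation(traj, superpose=False)
        assert c.correlation[0, 1] == pytest.approx(0.8, abs=0.05)

    def test_too_few_frames_rejected(self):
        spec = sim.TrajectorySimSpec(n_residues=3, n_frames=5,
                                     communities=(), inter_corr=0.0, seed=1)
        traj = sim.simulate_trajectory(spec)
        with pytest.raises(ValidationError):
            net.generalized_correlation(traj, k=6, superpose=False)


class TestNetworkBuild:
    def test_edge_distances(self, jitter_traj):
        c = np.eye(jitter_traj.n_residues)
        c[0, 4] = c[4, 0] = 0.5
        c[0, 5] = c[5, 0] = 1.0
        g = net.build_network(c, jitter_traj)
        if g.graph.has_edge(0, 4):
            assert g.graph[0][4]["distance"] == pytest.approx(np.log(2), abs=1e-9)
        assert g.graph[0][5]["distance"] == 0.0 \
            if g.graph.has_edge(0, 5) else True

    def test_occupancy_threshold_monotonicity(self, jitter_traj):
        c = np.random.default_rng(1).uniform(0.2, 0.9,
                                             (jitter_traj.n_residues,) * 2)
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        loose = net.build_network(c, jitter_traj, occupancy=0.5)
        strict = net.build_network(c, jitter_traj, occupancy=0.9)
        assert set(strict.graph.edges).issubset(set(loose.graph.edges))


def _betweenness_oracle(g: nx.Graph) -> dict:
    """Exhaustive shortest-path enumeration on the weighted graph."""
    scores = {n: 0.0 for n in g}
    nodes = list(g)
    for si, s in enumerate(nodes):
        for t in nodes[si + 1:]:
            paths = list(nx.all_shortest_paths(g, s, t, weight="distance"))
            for p in paths:
                for v in p[1:-1]:
                    scores[v] += 1.0 / len(paths)
    n = len(nodes)
    norm = 2.0 / ((n - 1) * (n - 2))
    return {k: v * norm for k, v in scores.items()}


def _clique_pair_network():
    g = nx.Graph()
    for offset in (0, 5):
        for i in range(5):
            for j in range(i + 1, 5):
                g.add_edge(offset + i, offset + j, correlation=0.8,
                           distance=-np.log(0.8))
    g.add_edge(4, 5, correlation=0.3, distance=-np.log(0.3))
    c = np.eye(10)
    return net.CorrelationNetwork(residue_ids=list(range(1, 11)),
                                  correlation=c, graph=g)


class TestCommunities:
    def test_two_cliques_split_with_bridge_on_top(self):
        network = _clique_pair_network()
        part = net.communities(network)
        assert part.n_communities == 2
        labels = part.labels
        assert len({labels[i] for i in range(5)}) == 1
        assert len({labels[i] for i in range(5, 10)}) == 1
        top2 = sorted(part.betweenness, key=part.betweenness.get,
                      reverse=True)[:2]
        assert set(top2) == {4, 5}
        oracle = _betweenness_oracle(network.graph)
        for n_ in network.graph:
            assert part.betweenness[n_] == pytest.approx(oracle[n_], abs=1e-9)
        assert part.coupling[(0, 1)] == pytest.approx(0.3)

    def test_path_graph_center_has_max_betweenness(self):
        g = nx.Graph()
        g.add_edge(0, 1, correlation=0.5, distance=np.log(2))
        g.add_edge(1, 2, correlation=0.5, distance=np.log(2))
        network = net.CorrelationNetwork(residue_ids=[1, 2, 3],
                                         correlation=np.eye(3), graph=g)
        part = net.communities(network)
        assert max(part.betweenness, key=part.betweenness.get) == 1

    def test_single_community_comes_back_with_note(self):
        g = nx.complete_graph(4)
        for i, j in g.edges:
            g[i][j]["correlation"] = 0.8
            g[i][j]["distance"] = -np.log(0.8)
        network = net.CorrelationNetwork(residue_ids=[1, 2, 3, 4],
                                         correlation=np.eye(4), graph=g)
        part = net.communities(network)
        assert part.n_communities == 1
        assert "single community" in part.note
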