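"""Network construction and community detection: brute-force oracles,
exhaustive modularity search, and the co-membership verdict."""

import numpy as np
import networkx as nx
import pytest

from rsfpkit import dynnet, synthgen, trajio

import oracles


def _nodemap_for(traj):
    return trajio.build_node_map(traj)


class TestContactOccupancy:
    def test_static_pairs_inside_and_outside_cutoff(self, toy_trajectory_factory):
        coords = np.zeros((4, 3, 3))
        coords[:, 1, 0] = 3.0  # 3 Å from atom 0
        coords[:, 2, 0] = 8.0  # 5 Å from atom 1
        traj = toy_trajectory_factory(coords)
        occ = dynnet.contact_occupancy(traj, _nodemap_for(traj))
        assert occ[0, 1] == 1.0
        assert occ[1, 2] == 0.0

    def test_matches_bruteforce_all_pairs_loop(self, toy_trajectory_factory):
        rng = np.random.default_rng(12)
        # 6 nodes x 2 atoms, 50 frames
        coords = rng.uniform(0, 6, size=(50, 12, 3))
        resids = np.repeat(np.arange(1, 7), 2)
        traj = toy_trajectory_factory(coords, resids=resids)
        nodemap = _nodemap_for(traj)
        occ = dynnet.contact_occupancy(traj, nodemap, cutoff=4.0)
        members = [list(n.members) for n in nodemap.nodes]
        expected = oracles.brute_force_occupancy(coords, members, 4.0)
        np.testing.assert_allclose(occ, expected, atol=1e-12)

    def test_symmetric(self, toy_trajectory_factory):
        rng = np.random.default_rng(3)
        traj = toy_trajectory_factory(rng.uniform(0, 5, size=(10, 6, 3)))
        occ = dynnet.contact_occupancy(traj, _nodemap_for(traj))
        np.testing.assert_allclose(occ, occ.T, atol=1e-12)


class TestCorrelationMatrix:
    def test_identical_and_mirrored_motion(self, toy_trajectory_factory):
        rng = np.random.default_rng(5)
        base = np.cumsum(rng.normal(size=(20, 3)), axis=0)
        coords = np.zeros((20, 3, 3))
        coords[:, 0] = base
        coords[:, 1] = base + 10.0  # identical displacements
        coords[:, 2] = -base  # mirrored displacements
        traj = toy_trajectory_factory(coords)
        c = dynnet.correlation_matrix(traj, _nodemap_for(traj))
        assert c[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert c[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_direct_formula_on_small_case(self, toy_trajectory_factory):
        rng = np.random.default_rng(8)
        coords = rng.normal(size=(5, 4, 3))
        traj = toy_trajectory_factory(coords)
        nodemap = _nodemap_for(traj)
        c = dynnet.correlation_matrix(traj, nodemap)
        expected = oracles.direct_correlation(nodemap.representatives(traj))
        np.testing.assert_allclose(c, expected, atol=1e-12)
        np.testing.assert_allclose(c, c.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(c), 1.0, atol=1e-12)

    def test_zero_variance_node_warns_and_gets_zero(self, toy_trajectory_factory):
        rng = np.random.default_rng(9)
        coords = rng.normal(size=(10, 3, 3))
        coords[:, 2] = 5.0  # static node
        traj = toy_trajectory_factory(coords)
        with pytest.warns(UserWarning, match="zero displacement variance"):
            c = dynnet.correlation_matrix(traj, _nodemap_for(traj))
        assert c[0, 2] == 0.0 and c[2, 2] == 1.0

    def test_too_few_frames_rejected(self, toy_trajectory_factory):
        traj = toy_trajectory_factory(np.zeros((2, 3, 3)))
        with pytest.raises(ValueError):
            dynnet.correlation_matrix(traj, _nodemap_for(traj))


class TestBuildGraph:
    def _nodemap(self, n):
        traj_coords = np.zeros((1, n, 3))
        meta_traj = trajio.Trajectory(
            coords=traj_coords,
            atom_meta=__import__("pandas").DataFrame(
                {
                    "name": [f"C{i}" for i in range(n)],
                    "residue_index": np.arange(1, n + 1),
                    "residue_name": ["GLY"] * n,
                    "chain": ["A"] * n,
                }
            ),
        )
        return trajio.build_node_map(meta_traj)

    def test_edge_weight_is_minus_log_abs_correlation(self):
        nodemap = self._nodemap(3)
        occ = np.ones((3, 3))
        corr = np.full((3, 3), 0.5)
        g = dynnet.build_graph(occ, corr, nodemap)
        assert g[0][2]["weight"] == pytest.approx(-np.log(0.5), abs=1e-12)

    def test_occupancy_threshold_is_strict(self):
        nodemap = self._nodemap(3)
        corr = np.full((3, 3), 0.9)
        occ = np.full((3, 3), 0.75)  # exactly at threshold: "more than 75 %"
        g = dynnet.build_graph(occ, corr, nodemap)
        assert g.number_of_edges() == 0
        occ = np.full((3, 3), 0.750001)
        g = dynnet.build_graph(occ, corr, nodemap)
        assert g.has_edge(0, 2)

    def test_neighbor_pairs_excluded_even_at_full_occupancy(self):
        nodemap = self._nodemap(3)
        occ = np.ones((3, 3))
        corr = np.full((3, 3), 0.9)
        g = dynnet.build_graph(occ, corr, nodemap)
        assert not g.has_edge(0, 1) and not g.has_edge(1, 2)
        assert g.has_edge(0, 2)
        g_all = dynnet.build_graph(
            occ, corr, nodemap, dynnet.NetworkConfig(exclude_neighbors=False)
        )
        assert g_all.has_edge(0, 1)

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(21)
        nodemap = self._nodemap(8)
        occ = rng.uniform(0, 1, size=(8, 8))
        occ = (occ + occ.T) / 2
        corr = rng.uniform(-1, 1, size=(8, 8))
        corr = (corr + corr.T) / 2
        previous = None
        for threshold in (0.2, 0.4, 0.6, 0.8):
            edges = set(
                dynnet.build_graph(
                    occ, corr, nodemap, dynnet.NetworkConfig(occupancy_threshold=threshold)
                ).edges
            )
            if previous is not None:
                assert edges <= previous
            previous = edges

    def test_config_validation(self):
        with pytest.raises(ValueError):
            dynnet.NetworkConfig(contact_cutoff=0.0)
        with pytest.raises(ValueError):
            dynnet.NetworkConfig(occupancy_threshold=1.0)


class TestDetectCommunities:
    def _clique_pair(self):
        g = nx.Graph()
        for block in (range(4), range(4, 8)):
            for i in block:
                for j in block:
                    if i < j:
                        g.add_edge(i, j, weight=-np.log(0.9), strength=0.9)
        g.add_edge(0, 4, weight=-np.log(0.1), strength=0.1)
        return g

    def test_two_cliques_split_at_weak_bridge(self):
        partition = dynnet.detect_communities(self._clique_pair())
        assert partition.communities() == [{0, 1, 2, 3}, {4, 5, 6, 7}]
        assert -0.5 <= partition.modularity <= 1.0

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("n", [8, 9])
    def test_modularity_equals_exhaustive_optimum_on_seeded_toys(self, seed, n):
        g = oracles.two_block_toy(seed, n)
        partition = dynnet.detect_communities(g)
        assert partition.modularity == pytest.approx(
            oracles.exhaustive_best_modularity(g), abs=1e-9
        )

    def test_edgeless_graph_gives_singletons_with_zero_modularity(self):
        g = nx.Graph()
        g.add_nodes_from(range(4))
        partition = dynnet.detect_communities(g)
        assert len(partition.communities()) == 4
        assert partition.modularity == 0.0

    def test_disconnected_components_are_never_merged(self):
        g = self._clique_pair()
        g.remove_edge(0, 4)
        partition = dynnet.detect_communities(g)
        comms = partition.communities()
        for component in nx.connected_components(g):
            assert any(comm <= component for comm in comms)
            assert not any(comm > component for comm in comms)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            dynnet.detect_communities(nx.Graph())


class TestVerdictAndReport:
    def _partitioned_case(self, same_group, seed=0):
        planted = synthgen.gen_trajectory(
            synthgen.TrajectorySpec(
                chromophore=synthgen.ChromophoreSpec(same_group=same_group),
                seed=seed,
            )
        )
        nodemap = trajio.build_node_map(planted.trajectory, planted.chromophore_table)
        occ = dynnet.contact_occupancy(planted.trajectory, nodemap)
        corr = dynnet.correlation_matrix(planted.trajectory, nodemap)
        partition = dynnet.detect_communities(dynnet.build_graph(occ, corr, nodemap))
        return planted, nodemap, partition

    def test_verdict_matches_planted_design(self):
        for same_group in (True, False):
            _, nodemap, partition = self._partitioned_case(same_group)
            assert dynnet.co_membership(partition, nodemap) is same_group

    def test_single_community_is_trivially_co_member(self):
        planted, nodemap, _ = self._partitioned_case(True)
        labels = {node.node_id: 0 for node in nodemap.nodes}
        partition = dynnet.CommunityPartition(labels=labels, modularity=0.0)
        assert dynnet.co_membership(partition, nodemap) is True

    def test_missing_chromophore_nodes_is_an_error(self, toy_trajectory_factory):
        traj = toy_trajectory_factory(np.zeros((1, 3, 3)))
        nodemap = trajio.build_node_map(traj)
        partition = dynnet.CommunityPartition(
            labels={n.node_id: 0 for n in nodemap.nodes}, modularity=0.0
        )
        with pytest.raises(ValueError):
            dynnet.co_membership(partition, nodemap)

    def test_report_lists_phenyl_community_and_flags_interest(self):
        planted, nodemap, partition = self._partitioned_case(True, seed=1)
        report = dynnet.community_report(partition, nodemap, residues_of_interest=[3])
        phenyl_comm = partition.labels[nodemap.chromophore_nodes["phenyl"]]
        in_comm = set(report[report["in_phenyl_community"]]["node_id"])
        assert in_comm == {
            n for n, c in partition.labels.items() if c == phenyl_comm
        }
        assert report[report["residue_of_interest"]]["residue_index"].tolist() == [3]
        # an empty interest list is still a valid report
        empty = dynnet.community_report(partition, nodemap)
        assert not empty["residue_of_interest"].any()

    def test_end_to_end_planted_recovery_single_case(self, planted_recovery):
        exact, verdict_ok = planted_recovery(seed=3, same_group=True)
        assert exact and verdict_ok
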