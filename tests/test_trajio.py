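"""Structure/trajectory round trips, Kabsch superposition against a
quaternion oracle, and node-map construction."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from rsfpkit import synthgen, trajio

import oracles


@pytest.fixture
def planted(tmp_path):
    p = synthgen.gen_trajectory(synthgen.TrajectorySpec(seed=5, n_frames=20))
    trajio.write_pdb(p.trajectory, tmp_path / "structure.pdb")
    trajio.write_xyz(p.trajectory, tmp_path / "trajectory.xyz")
    return p


class TestReadStructure:
    def test_pdb_round_trip_within_format_precision(self, planted, tmp_path):
        structure = trajio.read_structure(tmp_path / "structure.pdb")
        assert structure.n_frames == 1
        np.testing.assert_allclose(
            structure.coords[0], planted.trajectory.coords[0], atol=1e-3
        )
        pd.testing.assert_series_equal(
            structure.atom_meta["residue_index"],
            planted.trajectory.atom_meta["residue_index"],
        )
        assert list(structure.atom_meta["name"]) == list(
            planted.trajectory.atom_meta["name"]
        )

    def test_empty_file_is_an_error(self, tmp_path):
        empty = tmp_path / "empty.pdb"
        empty.write_text("")
        with pytest.raises(ValueError):
            trajio.read_structure(empty)

    def test_missing_file_is_an_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            trajio.read_structure(tmp_path / "nope.pdb")

    def test_toy_pdb_atoms_and_residue_indices(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(
            "ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1       2.000   2.000   3.000  1.00  0.00           C\n"
            "ATOM      3  N   GLY A   2       5.000   2.000   3.000  1.00  0.00           N\n"
            "END\n"
        )
        structure = trajio.read_structure(path)
        assert structure.n_atoms == 3
        assert list(structure.atom_meta["residue_index"]) == [1, 1, 2]
        np.testing.assert_allclose(structure.coords[0, 0], [1.0, 2.0, 3.0])


class TestReadTrajectory:
    def test_xyz_round_trip(self, planted, tmp_path):
        structure = trajio.read_structure(tmp_path / "structure.pdb")
        traj = trajio.read_trajectory(structure, tmp_path / "trajectory.xyz")
        assert traj.frame_count == planted.trajectory.n_frames
        np.testing.assert_allclose(
            traj.coords, planted.trajectory.coords, atol=1e-5
        )

    def test_atom_count_mismatch_is_an_error(self, planted, tmp_path):
        structure = trajio.read_structure(tmp_path / "structure.pdb")
        bad = tmp_path / "bad.xyz"
        bad.write_text("2\nframe 0\nC 0 0 0\nC 1 0 0\n")
        with pytest.raises(ValueError):
            trajio.read_trajectory(structure, bad)


class TestSuperpose:
    def _random_traj(self, toy_factory, seed=0, n=10, frames=4):
        rng = np.random.default_rng(seed)
        return toy_factory(rng.normal(size=(frames, n, 3)) * 3.0)

    def test_rigid_copy_aligns_to_zero_rmsd(self, toy_trajectory_factory):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(12, 3))
        rot = Rotation.random(random_state=2).as_matrix()
        moved = ref @ rot.T + np.array([5.0, -3.0, 2.0])
        traj = trajio.superpose(toy_trajectory_factory(np.stack([ref, moved])))
        rmsd = np.sqrt(((traj.coords[1] - traj.coords[0]) ** 2).sum(axis=1).mean())
        assert rmsd < 1e-8

    def test_identity_input_unchanged(self, toy_trajectory_factory):
        traj = self._random_traj(toy_trajectory_factory, frames=1)
        out = trajio.superpose(traj)
        np.testing.assert_allclose(out.coords, traj.coords, atol=1e-10)

    def test_idempotent(self, toy_trajectory_factory):
        traj = self._random_traj(toy_trajectory_factory, seed=3)
        once = trajio.superpose(traj)
        twice = trajio.superpose(once)
        np.testing.assert_allclose(twice.coords, once.coords, atol=1e-8)

    def test_matches_quaternion_oracle_and_never_increases_rmsd(
        self, toy_trajectory_factory
    ):
        traj = self._random_traj(toy_trajectory_factory, seed=7, frames=6)
        aligned = trajio.superpose(traj)
        ref = traj.coords[0]
        for f in range(1, traj.n_frames):
            before = np.sqrt(((traj.coords[f] - ref) ** 2).sum(axis=1).mean())
            after = np.sqrt(((aligned.coords[f] - ref) ** 2).sum(axis=1).mean())
            oracle = oracles.quaternion_min_rmsd(traj.coords[f], ref)
            assert after <= before + 1e-12
            assert after == pytest.approx(oracle, abs=1e-8)

    def test_collinear_reference_warns_and_skips(self, toy_trajectory_factory):
        line = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        coords = np.stack([line, line + 1.0])
        with pytest.warns(UserWarning, match="degenerate"):
            out = trajio.superpose(toy_trajectory_factory(coords))
        np.testing.assert_array_equal(out.coords, coords)


class TestNodeMap:
    def test_plain_residues_counts_and_neighbor_pairs(self, toy_trajectory_factory):
        traj = toy_trajectory_factory(np.zeros((1, 5, 3)))
        nodemap = trajio.build_node_map(traj)
        assert nodemap.n_nodes == 5
        assert len(nodemap.neighbor_pairs) == 4

    def test_chromophore_adds_three_nodes(self):
        planted = synthgen.gen_trajectory(
            synthgen.TrajectorySpec(n_residues=5, n_frames=5, seed=0)
        )
        nodemap = trajio.build_node_map(
            planted.trajectory, planted.chromophore_table
        )
        assert nodemap.n_nodes == 8
        assert set(nodemap.chromophore_nodes) == {"imidazolinone", "phenyl", "his66"}

    def test_neighbor_pairs_match_bruteforce_enumeration(self):
        planted = synthgen.gen_trajectory(
            synthgen.TrajectorySpec(n_residues=7, n_frames=5, seed=1)
        )
        nodemap = trajio.build_node_map(
            planted.trajectory, planted.chromophore_table
        )
        expected = set()
        for a in nodemap.nodes:
            for b in nodemap.nodes:
                if a.node_id >= b.node_id or a.chain != b.chain:
                    continue
                if abs(a.residue_index - b.residue_index) <= 1:
                    expected.add((a.node_id, b.node_id))
        assert nodemap.neighbor_pairs == expected

    def test_members_partition_mapped_atoms(self):
        planted = synthgen.gen_trajectory(synthgen.TrajectorySpec(seed=2, n_frames=5))
        nodemap = trajio.build_node_map(
            planted.trajectory, planted.chromophore_table
        )
        all_members = [a for node in nodemap.nodes for a in node.members]
        assert len(all_members) == len(set(all_members))
        assert len(all_members) == planted.trajectory.n_atoms

    def test_missing_chromophore_atoms_is_an_error(self):
        planted = synthgen.gen_trajectory(synthgen.TrajectorySpec(seed=3, n_frames=5))
        table = {
            "resname": "CRO",
            "fragments": {
                "imidazolinone": ["NOPE"],
                "phenyl": ["P1"],
                "his66": ["H1"],
            },
        }
        with pytest.raises(ValueError, match="not found"):
            trajio.build_node_map(planted.trajectory, table)

    def test_fragment_table_must_name_three_fragments(self):
        with pytest.raises(ValueError):
            trajio.normalize_chromophore_table({"phenyl": ["P1"], "his66": ["H1"]})
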