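import warnings

import numpy as np
import pandas as pd
import pytest

from rsfpkit import dynnet, synthgen, trajio


def make_toy_trajectory(coords, names=None, resids=None):
    """Trajectory from a raw (frames, atoms, 3) array with 1-atom residues
    by default."""
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[1]
    names = names or [f"C{i + 1}" for i in range(n_atoms)]
    resids = resids if resids is not None else list(range(1, n_atoms + 1))
    meta = pd.DataFrame(
        {
            "name": names,
            "residue_index": resids,
            "residue_name": ["GLY"] * n_atoms,
            "chain": ["A"] * n_atoms,
        }
    )
    return trajio.Trajectory(coords=coords, atom_meta=meta)


def run_planted_recovery(
    seed, same_group, n_residues=12, group_labels=None, noise_sigma=0.1, n_frames=300
):
    """Full pipeline on a planted trajectory; returns (exact_recovery,
    verdict_matches_design)."""
    spec = synthgen.TrajectorySpec(
        chromophore=synthgen.ChromophoreSpec(same_group=same_group),
        n_residues=n_residues,
        group_labels=group_labels,
        noise_sigma=noise_sigma,
        n_frames=n_frames,
        seed=seed,
    )
    planted = synthgen.gen_trajectory(spec)
    nodemap = trajio.build_node_map(planted.trajectory, planted.chromophore_table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        traj = trajio.superpose(planted.trajectory)
    occupancy = dynnet.contact_occupancy(traj, nodemap)
    correlation = dynnet.correlation_matrix(traj, nodemap)
    graph = dynnet.build_graph(occupancy, correlation, nodemap)
    partition = dynnet.detect_communities(graph)
    detected = {nodemap.nodes[i].label: c for i, c in partition.labels.items()}
    planted_labels = planted.node_groups
    mapping: dict[int, int] = {}
    exact = True
    for label, community in detected.items():
        group = planted_labels[label]
        if community in mapping and mapping[community] != group:
            exact = False
        mapping[community] = group
    exact = exact and len(set(detected.values())) == len(set(planted_labels.values()))
    verdict_ok = dynnet.co_membership(partition, nodemap) == same_group
    return exact, verdict_ok


@pytest.fixture
def toy_trajectory_factory():
    return make_toy_trajectory


@pytest.fixture
def planted_recovery():
    return run_planted_recovery
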