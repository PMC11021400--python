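"""Dynamic network analysis of residue motions.

The network follows the dynamic-network-analysis convention for protein
trajectories: nodes are residues (plus three chromophore fragments), two
nodes are joined by an edge when any pair of their atoms is closer than a
cutoff in more than a threshold fraction of frames (default: 4 Å in more
than 75 % of frames, sequence neighbours excluded), and each edge is
weighted by w_ij = −log|C_ij| from the dynamical cross-correlation of node
displacements.  Communities are cut with Girvan–Newman edge-betweenness
removal, selecting the partition of maximal Newman–Girvan modularity.

The isomerisation-competence verdict of this analysis is co-membership:
the chromophore's phenyl fragment and the His66-derived fragment must land
in the same community.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .trajio import NodeMap, Trajectory

__all__ = [
    "NetworkConfig",
    "CommunityPartition",
    "contact_occupancy",
    "correlation_matrix",
    "build_graph",
    "detect_communities",
    "co_membership",
    "community_report",
    "write_graph",
    "write_partition",
]

#: floor on |C| before taking −log, capping edge weights at ~13.8
MIN_ABS_CORRELATION = 1e-6


@dataclass(frozen=True)
class NetworkConfig:
    contact_cutoff: float = 4.0  # Å
    occupancy_threshold: float = 0.75  # strict: occupancy must exceed this
    exclude_neighbors: bool = True

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be > 0")
        if not (0.0 < self.occupancy_threshold < 1.0):
            raise ValueError("occupancy_threshold must be in (0, 1)")


@dataclass
class CommunityPartition:
    labels: dict[int, int]  # node id -> community id
    modularity: float

    def communities(self) -> list[set[int]]:
        out: dict[int, set[int]] = {}
        for node, comm in self.labels.items():
            out.setdefault(comm, set()).add(node)
        return [out[c] for c in sorted(out)]


def contact_occupancy(
    traj: Trajectory, nodemap: NodeMap, cutoff: float = 4.0
) -> np.ndarray:
    """Fraction of frames in which the minimum inter-atom distance between
    two nodes' member atoms is below ``cutoff``.  Diagonal is set to NaN.
    """
    from scipy.spatial.distance import cdist

    n = nodemap.n_nodes
    members = [np.fromiter(node.members, dtype=int) for node in nodemap.nodes]
    counts = np.zeros((n, n))
    for f in range(traj.n_frames):
        frame = traj.coords[f]
        d = cdist(frame, frame)
        for i in range(n):
            mi = members[i]
            for j in range(i + 1, n):
                if d[np.ix_(mi, members[j])].min() < cutoff:
                    counts[i, j] += 1
    occ = counts / traj.n_frames
    occ = occ + occ.T
    np.fill_diagonal(occ, np.nan)
    return occ


def correlation_matrix(traj: Trajectory, nodemap: NodeMap) -> np.ndarray:
    """Dynamical cross-correlation matrix of node representatives.

    C_ij = <dr_i · dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>) with dr the
    displacement of the node representative from its trajectory mean
    (scalar dot-product correlation of the 3-D displacement vectors).
    Zero-variance nodes get correlation 0 with a warning; the diagonal is 1.
    """
    if traj.n_frames < 3:
        raise ValueError("correlation needs at least 3 frames")
    reps = nodemap.representatives(traj)  # (F, n, 3)
    dr = reps - reps.mean(axis=0, keepdims=True)
    inner = np.einsum("fix,fjx->ij", dr, dr)
    var = np.diag(inner).copy()
    zero = var <= 0.0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} node(s) have zero displacement variance; "
            "their correlations are set to 0",
            stacklevel=2,
        )
        var[zero] = 1.0
    c = inner / np.sqrt(np.outer(var, var))
    c[zero, :] = 0.0
    c[:, zero] = 0.0
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def build_graph(
    occupancy: np.ndarray,
    correlation: np.ndarray,
    nodemap: NodeMap,
    config: NetworkConfig | None = None,
) -> nx.Graph:
    """Occupancy-filtered, correlation-weighted network.

    Edge (i, j) exists iff occupancy strictly exceeds the threshold and the
    pair is not sequence-adjacent (when exclusion is on).  Edges carry
    ``occupancy``, ``correlation``, ``weight`` = −log|C_ij| (|C| floored at
    1e-6) and ``strength`` = |C_ij| (= exp(−weight)).
    """
    config = config or NetworkConfig()
    n = nodemap.n_nodes
    if occupancy.shape != (n, n) or correlation.shape != (n, n):
        raise ValueError("occupancy/correlation shape does not match node map")
    g = nx.Graph()
    for node in nodemap.nodes:
        g.add_node(node.node_id, label=node.label)
    for i in range(n):
        for j in range(i + 1, n):
            if not occupancy[i, j] > config.occupancy_threshold:
                continue
            if config.exclude_neighbors and (i, j) in nodemap.neighbor_pairs:
                continue
            abs_c = max(abs(float(correlation[i, j])), MIN_ABS_CORRELATION)
            g.add_edge(
                i,
                j,
                occupancy=float(occupancy[i, j]),
                correlation=float(correlation[i, j]),
                weight=float(-np.log(abs_c)),
                strength=abs_c,
            )
    return g


def _most_valuable_edge(g: nx.Graph) -> tuple:
    """Highest weighted-betweenness edge; ties broken by the
    lexicographically smallest (sorted) edge tuple."""
    bc = nx.edge_betweenness_centrality(g, weight="weight")
    best = max(bc.values())
    candidates = [tuple(sorted(e)) for e, v in bc.items() if v >= best - 1e-12]
    return min(candidates)


def _modularity(g: nx.Graph, communities) -> float:
    return nx.community.modularity(g, communities, weight="strength")


def detect_communities(graph: nx.Graph) -> CommunityPartition:
    """Girvan–Newman community detection with modularity model selection.

    Edge betweenness is computed on ``weight`` (= −log|C|, a distance);
    modularity uses ``strength`` (= |C|) as the edge strength.  The
    partition along the removal dendrogram with maximal modularity is
    returned; connected components are never merged.  An edgeless graph
    yields singleton communities with Q = 0.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if graph.number_of_edges() == 0:
        labels = {n: i for i, n in enumerate(sorted(graph.nodes))}
        return CommunityPartition(labels=labels, modularity=0.0)

    best_q = -np.inf
    best: list[set] | None = None
    initial = [set(c) for c in nx.connected_components(graph)]
    for partition in [initial] + [
        [set(c) for c in p]
        for p in nx.community.girvan_newman(graph, most_valuable_edge=_most_valuable_edge)
    ]:
        q = _modularity(graph, partition)
        if q > best_q + 1e-12:
            best_q = q
            best = partition

    assert best is not None
    ordered = sorted(best, key=min)
    labels: dict[int, int] = {}
    for comm_id, members in enumerate(ordered):
        for node in members:
            labels[node] = comm_id
    return CommunityPartition(labels=labels, modularity=float(best_q))


def co_membership(partition: CommunityPartition, nodemap: NodeMap) -> bool:
    """Isomerisation-competence verdict: True iff the phenyl fragment and
    the His66-derived fragment share a community."""
    for frag in ("phenyl", "his66"):
        if frag not in nodemap.chromophore_nodes:
            raise ValueError(f"node map lacks chromophore fragment '{frag}'")
    phenyl = nodemap.chromophore_nodes["phenyl"]
    his66 = nodemap.chromophore_nodes["his66"]
    if phenyl not in partition.labels or his66 not in partition.labels:
        raise ValueError("partition does not cover the chromophore nodes")
    return partition.labels[phenyl] == partition.labels[his66]


def community_report(
    partition: CommunityPartition,
    nodemap: NodeMap,
    residues_of_interest: list[int] | None = None,
) -> pd.DataFrame:
    """Members of the community containing the phenyl fragment, with a flag
    per residue of interest (e.g. the 163/161/177 positions)."""
    interest = set(residues_of_interest or [])
    if "phenyl" in nodemap.chromophore_nodes:
        focus = partition.labels[nodemap.chromophore_nodes["phenyl"]]
    else:
        focus = None
    rows = []
    for node in nodemap.nodes:
        comm = partition.labels[node.node_id]
        rows.append(
            {
                "node_id": node.node_id,
                "label": node.label,
                "residue_index": node.residue_index,
                "community": comm,
                "in_phenyl_community": focus is not None and comm == focus,
                "residue_of_interest": node.residue_index in interest,
            }
        )
    return pd.DataFrame(rows)


def write_graph(graph: nx.Graph, graphml_path=None, edge_tsv_path=None) -> None:
    if graphml_path is not None:
        nx.write_graphml(graph, graphml_path)
    if edge_tsv_path is not None:
        rows = [
            {
                "i": i,
                "j": j,
                "occupancy": d["occupancy"],
                "correlation": d["correlation"],
                "weight": d["weight"],
            }
            for i, j, d in graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["i", "j", "occupancy", "correlation", "weight"]).to_csv(
            edge_tsv_path, sep="\t", index=False
        )


def write_partition(
    partition: CommunityPartition, nodemap: NodeMap, path
) -> None:
    rows = [
        {"node": node.label, "community": partition.labels[node.node_id]}
        for node in nodemap.nodes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
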