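"""Structure/trajectory I/O, superposition and atom-to-node mapping.

Coordinates live in a plain ``(n_frames, n_atoms, 3)`` float array with a
pandas table of per-atom metadata alongside.  File parsing is delegated to
MDAnalysis; this module only normalises the result into :class:`Trajectory`
and adds the network-specific notion of a :class:`NodeMap` — one node per
amino acid, three nodes for the chromophore, and the list of sequence-adjacent
node pairs that the dynamic network excludes from edge building.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "Node",
    "NodeMap",
    "read_structure",
    "read_trajectory",
    "superpose",
    "build_node_map",
    "load_chromophore_table",
]

#: metadata columns every Trajectory carries, in order
ATOM_META_COLUMNS = ("name", "residue_index", "residue_name", "chain")


@dataclass
class Trajectory:
    """A coordinate trajectory plus per-atom metadata.

    Parameters
    ----------
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in Å.
    atom_meta
        DataFrame with columns ``name, residue_index, residue_name, chain``;
        one row per atom, in atom order.
    """

    coords: np.ndarray
    atom_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(
                f"coords must have shape (frames, atoms, 3), got {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates contain non-finite values")
        missing = [c for c in ATOM_META_COLUMNS if c not in self.atom_meta.columns]
        if missing:
            raise ValueError(f"atom_meta missing columns: {missing}")
        if len(self.atom_meta) != self.coords.shape[1]:
            raise ValueError(
                f"atom_meta has {len(self.atom_meta)} rows for "
                f"{self.coords.shape[1]} atoms"
            )
        self.atom_meta = self.atom_meta.reset_index(drop=True)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    #: alias used in reports
    frame_count = n_frames

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]


@dataclass(frozen=True)
class Node:
    """One network node: a residue or a chromophore fragment."""

    node_id: int
    label: str
    members: tuple  # atom indices into the trajectory
    residue_index: int
    chain: str


@dataclass
class NodeMap:
    """Atom-to-node assignment for the dynamic network.

    ``neighbor_pairs`` holds sequence-adjacent node-id pairs (as sorted
    tuples); ``chromophore_nodes`` maps fragment names
    (imidazolinone/phenyl/his66) to node ids when a chromophore table was
    supplied.
    """

    nodes: list[Node]
    neighbor_pairs: set[tuple[int, int]]
    chromophore_nodes: dict[str, int] = field(default_factory=dict)
    representative: str = "cog"  # "cog" or "ca"

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for node in self.nodes:
            if not node.members:
                raise ValueError(f"node {node.label} has no member atoms")
            overlap = seen.intersection(node.members)
            if overlap:
                raise ValueError(f"atoms {sorted(overlap)} assigned to two nodes")
            seen.update(node.members)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def labels(self) -> list[str]:
        return [n.label for n in self.nodes]

    def representatives(self, traj: Trajectory) -> np.ndarray:
        """Per-frame node representative coordinates, shape (frames, nodes, 3).

        The default representative is the centre of geometry of the node's
        member atoms; ``representative="ca"`` uses the CA atom for ordinary
        residues (fragments fall back to the centre of geometry).
        """
        reps = np.empty((traj.n_frames, self.n_nodes, 3))
        names = traj.atom_meta["name"].to_numpy()
        for node in self.nodes:
            members = np.fromiter(node.members, dtype=int)
            sel = members
            if self.representative == "ca":
                ca = members[names[members] == "CA"]
                if ca.size == 1:
                    sel = ca
            reps[:, node.node_id, :] = traj.coords[:, sel, :].mean(axis=1)
        return reps


def _meta_from_universe(u) -> pd.DataFrame:
    atoms = u.atoms
    try:
        chains = atoms.chainIDs
    except Exception:
        try:
            chains = atoms.segids
        except Exception:
            chains = np.array(["A"] * len(atoms))
    chains = ["A" if str(c).strip() in ("", "SYSTEM") else str(c).strip() for c in chains]
    try:
        resnames = [str(r) for r in atoms.resnames]
    except Exception:
        resnames = ["UNK"] * len(atoms)
    return pd.DataFrame(
        {
            "name": [str(n) for n in atoms.names],
            "residue_index": np.asarray(atoms.resids, dtype=int),
            "residue_name": resnames,
            "chain": chains,
        }
    )


def read_structure(path: str | Path) -> Trajectory:
    """Read a single-model PDB into a one-frame :class:`Trajectory`."""
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty structure file")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as exc:  # pragma: no cover - message path
            raise ValueError(f"{path}: could not parse structure ({exc})") from exc
    if len(u.atoms) == 0:
        raise ValueError(f"{path}: no atoms parsed")
    coords = u.atoms.positions.astype(float)[None, :, :]
    return Trajectory(coords=coords, atom_meta=_meta_from_universe(u))


def read_trajectory(structure: Trajectory, path: str | Path) -> Trajectory:
    """Read a multi-frame XYZ (or DCD) file onto an existing structure.

    The structure supplies atom metadata; every frame in the file must have
    the structure's atom count.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    n_atoms = structure.n_atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe.empty(n_atoms=n_atoms, trajectory=True)
            u.load_new(str(path))
            frames = [ts.positions.astype(float).copy() for ts in u.trajectory]
        except Exception as exc:
            raise ValueError(
                f"{path}: could not read trajectory for {n_atoms} atoms ({exc})"
            ) from exc
    if not frames:
        raise ValueError(f"{path}: trajectory contains no frames")
    coords = np.stack(frames, axis=0)
    if coords.shape[1] != n_atoms:
        raise ValueError(
            f"{path}: frame atom count {coords.shape[1]} != structure {n_atoms}"
        )
    return Trajectory(coords=coords, atom_meta=structure.atom_meta.copy())


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal rotation (proper, unweighted) aligning centred ``mobile``
    onto centred ``reference``."""
    h = mobile.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    correction = np.diag([1.0, 1.0, d])
    return u @ correction @ vt


def superpose(traj: Trajectory, reference_frame_index: int = 0) -> Trajectory:
    """Rigid-body align every frame onto the reference frame (Kabsch, all
    atoms, unweighted).

    A degenerate (collinear) reference cannot fix all rotational degrees of
    freedom; the trajectory is returned unaligned with a warning.
    """
    ref = traj.coords[reference_frame_index]
    ref_centered = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(ref_centered, tol=1e-8) < 2:
        warnings.warn(
            "reference frame is degenerate (collinear atoms); superposition skipped",
            stacklevel=2,
        )
        return Trajectory(coords=traj.coords.copy(), atom_meta=traj.atom_meta.copy())
    out = np.empty_like(traj.coords)
    ref_com = ref.mean(axis=0)
    for f in range(traj.n_frames):
        frame = traj.coords[f]
        com = frame.mean(axis=0)
        rot = kabsch_rotation(frame - com, ref_centered)
        out[f] = (frame - com) @ rot + ref_com
    return Trajectory(coords=out, atom_meta=traj.atom_meta.copy())


def load_chromophore_table(path: str | Path) -> dict:
    """Load a chromophore fragment table from JSON.

    Accepted forms::

        {"resname": "CRO", "fragments": {"phenyl": ["P1", ...], ...}}
        {"phenyl": ["P1", ...], "his66": [...], "imidazolinone": [...]}
    """
    with open(path) as fh:
        table = json.load(fh)
    return normalize_chromophore_table(table)


def normalize_chromophore_table(table: Mapping) -> dict:
    if "fragments" in table:
        fragments = dict(table["fragments"])
        resname = table.get("resname", "CRO")
    else:
        fragments = {k: v for k, v in table.items() if k != "resname"}
        resname = table.get("resname", "CRO")
    if set(fragments) != {"imidazolinone", "phenyl", "his66"}:
        raise ValueError(
            "chromophore table must name exactly the fragments "
            f"imidazolinone/phenyl/his66, got {sorted(fragments)}"
        )
    flat: list[str] = []
    for names in fragments.values():
        flat.extend(names)
    if len(flat) != len(set(flat)):
        raise ValueError("chromophore fragments must use disjoint atom name sets")
    return {"resname": resname, "fragments": {k: list(v) for k, v in fragments.items()}}


# fragment order fixed so node ids are deterministic
FRAGMENT_ORDER = ("imidazolinone", "phenyl", "his66")


def build_node_map(
    traj: Trajectory,
    chromophore_table: Mapping | None = None,
    representative: str = "cog",
) -> NodeMap:
    """Build the network node map: one node per amino acid, three nodes for
    the chromophore residue, and sequence-neighbour exclusion pairs.

    The three chromophore nodes are mutual neighbours and each is a
    neighbour of the residues flanking the chromophore in sequence.
    """
    meta = traj.atom_meta
    table = (
        normalize_chromophore_table(chromophore_table)
        if chromophore_table is not None
        else None
    )
    cro_resname = table["resname"] if table else None

    nodes: list[Node] = []
    chromophore_nodes: dict[str, int] = {}
    # residues in (chain, resid) order of first appearance
    residue_keys: list[tuple[str, int]] = []
    seen_res: set[tuple[str, int]] = set()
    for chain, resid in zip(meta["chain"], meta["residue_index"]):
        key = (str(chain), int(resid))
        if key not in seen_res:
            seen_res.add(key)
            residue_keys.append(key)

    names = meta["name"].to_numpy()
    chains = meta["chain"].to_numpy()
    resids = meta["residue_index"].to_numpy()
    resnames = meta["residue_name"].to_numpy()

    cro_keys: set[tuple[str, int]] = set()
    for chain, resid in residue_keys:
        mask = (chains == chain) & (resids == resid)
        resname = str(resnames[mask][0])
        if table and resname == cro_resname:
            cro_keys.add((chain, resid))
            atom_idx = np.flatnonzero(mask)
            name_to_idx = {str(names[i]): i for i in atom_idx}
            for frag in FRAGMENT_ORDER:
                frag_names = table["fragments"][frag]
                missing = [n for n in frag_names if n not in name_to_idx]
                if missing:
                    raise ValueError(
                        f"chromophore fragment '{frag}' atoms not found: {missing}"
                    )
                node_id = len(nodes)
                nodes.append(
                    Node(
                        node_id=node_id,
                        label=frag,
                        members=tuple(int(name_to_idx[n]) for n in frag_names),
                        residue_index=resid,
                        chain=chain,
                    )
                )
                chromophore_nodes[frag] = node_id
        else:
            node_id = len(nodes)
            nodes.append(
                Node(
                    node_id=node_id,
                    label=f"{resname}{resid}",
                    members=tuple(int(i) for i in np.flatnonzero(mask)),
                    residue_index=resid,
                    chain=chain,
                )
            )
    if table and not chromophore_nodes:
        raise ValueError(
            f"no residue named '{cro_resname}' found for the chromophore table"
        )

    neighbor_pairs: set[tuple[int, int]] = set()

    def add_pair(a: int, b: int) -> None:
        if a != b:
            neighbor_pairs.add((min(a, b), max(a, b)))

    by_residue: dict[tuple[str, int], list[int]] = {}
    for node in nodes:
        by_residue.setdefault((node.chain, node.residue_index), []).append(node.node_id)

    for (chain, resid), ids in by_residue.items():
        # chromophore fragments of one residue are mutual neighbours
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                add_pair(a, b)
        for other in ((chain, resid - 1), (chain, resid + 1)):
            for a in ids:
                for b in by_residue.get(other, ()):
                    add_pair(a, b)

    return NodeMap(
        nodes=nodes,
        neighbor_pairs=neighbor_pairs,
        chromophore_nodes=chromophore_nodes,
        representative=representative,
    )


def write_pdb(traj: Trajectory, path: str | Path, frame: int = 0) -> None:
    """Write one frame as a single-model PDB (via MDAnalysis)."""
    import MDAnalysis as mda

    meta = traj.atom_meta
    n = traj.n_atoms
    u = mda.Universe.empty(
        n_atoms=n,
        n_residues=len(meta[["chain", "residue_index"]].drop_duplicates()),
        atom_resindex=_residue_codes(meta),
        trajectory=True,
    )
    u.add_TopologyAttr("names", meta["name"].tolist())
    res_meta = meta.drop_duplicates(["chain", "residue_index"])
    u.add_TopologyAttr("resids", res_meta["residue_index"].tolist())
    u.add_TopologyAttr("resnames", res_meta["residue_name"].tolist())
    u.add_TopologyAttr("chainIDs", meta["chain"].tolist())
    u.add_TopologyAttr("segids", ["A"])
    u.add_TopologyAttr("elements", [_element_guess(nm) for nm in meta["name"]])
    u.atoms.positions = traj.coords[frame]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def _residue_codes(meta: pd.DataFrame) -> np.ndarray:
    keys = list(zip(meta["chain"], meta["residue_index"]))
    order: dict[tuple, int] = {}
    for k in keys:
        if k not in order:
            order[k] = len(order)
    return np.array([order[k] for k in keys])


def _element_guess(name: str) -> str:
    for ch in str(name):
        if ch.isalpha():
            return ch.upper()
    return "C"


def write_xyz(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-frame XYZ file; the comment line carries the frame index."""
    names = traj.atom_meta["name"].tolist()
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"frame {f}\n")
            for name, (x, y, z) in zip(names, traj.coords[f]):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")
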