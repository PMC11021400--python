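"""Synthetic inputs for every analysis stage.

The generator emulates the statistical structure the downstream estimators
assume, at desk scale:

* bead-residue trajectories with planted groups of collectively moving
  residues (a shared latent random-walk displacement per group, plus i.i.d.
  Gaussian noise) laid out so the contact graph is connected but the groups
  are separable;
* a three-fragment chromophore (imidazolinone / phenyl / his66 beads) whose
  fragments can be planted into the same or different motion groups, which
  is what the community co-membership criterion must recover;
* mono-exponential fluorescence decay traces I(t) = A·exp(−k·t) + c with
  additive noise, and repeated switching cycles with geometric per-cycle
  bleaching of the amplitude;
* single-site Henderson–Hasselbalch titration curves;
* bond-length-alternation samples from a three-component Gaussian mixture;
* paired before/after-illumination absorbance changes.

All randomness flows through one ``numpy.random.default_rng(seed)`` per
call, so fixed seeds reproduce outputs exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .trajio import Trajectory

__all__ = [
    "ContactLayout",
    "ChromophoreSpec",
    "TrajectorySpec",
    "KineticSpec",
    "PlantedTrajectory",
    "DecayTrace",
    "TitrationCurve",
    "SpectrumPair",
    "gen_trajectory",
    "gen_decay_trace",
    "gen_switch_cycles",
    "gen_titration",
    "gen_bla_samples",
    "gen_spectra_pair",
    "write_ground_truth",
    "write_trace_csv",
    "write_titration_csv",
]


@dataclass(frozen=True)
class ContactLayout:
    """Bead geometry (Å) controlling which residues are in contact.

    Each motion group occupies its own compact serpentine grid in the
    x-y plane with ``spacing`` between orthogonal neighbours; with the
    default 1.4 Å every pair inside a group of up to ~9 residues falls
    within the 4 Å contact range, so each group forms a near-complete
    contact subgraph (a dense community that modularity will not split).
    Consecutive groups are offset by ``group_gap`` along x; one displaced
    "reach" atom pair creates a single bridging contact between two
    non-sequence-adjacent residues of the two groups, keeping the contact
    graph connected but the communities separable.
    """

    spacing: float = 1.4
    group_gap: float = 12.0
    bridge_reach: float = 5.0
    atom_dz: float = 0.3  # intra-residue atom stacking along z


@dataclass(frozen=True)
class ChromophoreSpec:
    """Motion-group assignment of the three chromophore fragments.

    ``same_group=True`` plants the phenyl fragment and the his66 fragment in
    one group (the isomerisation-competent design); otherwise his66 is
    planted in ``other_group``.
    """

    phenyl_group: int = 0
    imidazolinone_group: int = 0
    same_group: bool = True
    other_group: int = 1

    def his66_group(self) -> int:
        return self.phenyl_group if self.same_group else self.other_group


@dataclass
class TrajectorySpec:
    n_residues: int = 12
    atoms_per_residue: int = 3
    group_labels: Sequence[int] | None = None  # default: two equal blocks
    shared_motion_amplitude: float | Sequence[float] = 0.05  # Å per step
    noise_sigma: float = 0.1  # Å
    n_frames: int = 300
    contact_layout: ContactLayout = field(default_factory=ContactLayout)
    chromophore: ChromophoreSpec | None = field(default_factory=ChromophoreSpec)
    seed: int = 0

    def resolved_labels(self) -> np.ndarray:
        if self.group_labels is None:
            half = self.n_residues // 2
            labels = np.array([0] * half + [1] * (self.n_residues - half))
        else:
            labels = np.asarray(list(self.group_labels), dtype=int)
        return labels

    def n_groups(self) -> int:
        labels = self.resolved_labels()
        groups = set(labels.tolist())
        if self.chromophore is not None:
            groups.update(
                {
                    self.chromophore.phenyl_group,
                    self.chromophore.imidazolinone_group,
                    self.chromophore.his66_group(),
                }
            )
        return len(groups)

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.atoms_per_residue < 1:
            raise ValueError("atoms_per_residue must be >= 1")
        labels = self.resolved_labels()
        if len(labels) != self.n_residues:
            raise ValueError("group_labels must give one label per residue")
        amps = np.atleast_1d(np.asarray(self.shared_motion_amplitude, dtype=float))
        if np.any(amps < 0):
            raise ValueError("shared_motion_amplitude must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_groups() > 1 and self.atoms_per_residue < 2:
            raise ValueError(
                "multi-group layouts need atoms_per_residue >= 2 "
                "(one atom is displaced to form the bridging contact)"
            )


@dataclass
class PlantedTrajectory:
    """A generated trajectory with its planted ground truth."""

    trajectory: Trajectory
    node_groups: dict[str, int]  # node label -> planted group
    chromophore_table: dict | None


FRAGMENT_PREFIX = {"imidazolinone": "I", "phenyl": "P", "his66": "H"}


def _group_amplitude(spec: TrajectorySpec, group: int, n_groups: int) -> float:
    amps = np.atleast_1d(np.asarray(spec.shared_motion_amplitude, dtype=float))
    if amps.size == 1:
        return float(amps[0])
    if amps.size < n_groups:
        raise ValueError("need one amplitude per group (or a scalar)")
    return float(amps[group])


def gen_trajectory(spec: TrajectorySpec) -> PlantedTrajectory:
    """Generate a bead trajectory with planted correlated-motion groups.

    Sites (residues plus the three chromophore fragments if requested) are
    laid out group by group on the serpentine grids of
    :class:`ContactLayout`; every site in group *g* is displaced each frame
    by the group's shared latent random walk ``a_g · f_g(t)`` (latent walks
    are orthogonalised across groups) plus i.i.d. Gaussian noise per atom.
    """
    spec.validate()
    lay = spec.contact_layout
    labels = spec.resolved_labels()
    rng = np.random.default_rng(spec.seed)

    # --- site bookkeeping -------------------------------------------------
    # each site: (label, resid, resname, group, atom_names)
    sites: list[dict] = []
    for i in range(spec.n_residues):
        sites.append(
            {
                "label": f"GLY{i + 1}",
                "resid": i + 1,
                "resname": "GLY",
                "group": int(labels[i]),
                "atom_names": [f"C{a + 1}" for a in range(spec.atoms_per_residue)],
            }
        )
    chromophore_table = None
    if spec.chromophore is not None:
        cro_resid = spec.n_residues + 1
        frag_groups = {
            "imidazolinone": spec.chromophore.imidazolinone_group,
            "phenyl": spec.chromophore.phenyl_group,
            "his66": spec.chromophore.his66_group(),
        }
        fragments = {}
        for frag, grp in frag_groups.items():
            names = [
                f"{FRAGMENT_PREFIX[frag]}{a + 1}"
                for a in range(spec.atoms_per_residue)
            ]
            fragments[frag] = names
            sites.append(
                {
                    "label": frag,
                    "resid": cro_resid,
                    "resname": "CRO",
                    "group": int(grp),
                    "atom_names": names,
                }
            )
        chromophore_table = {"resname": "CRO", "fragments": fragments}

    for idx, site in enumerate(sites):
        site["index"] = idx
    groups = sorted({s["group"] for s in sites})
    # --- reference geometry ----------------------------------------------
    # each group occupies a serpentine square-ish grid; chromophore
    # fragments are inserted at interior grid positions (2, 4, 6, ...) so
    # they keep several contacts with ordinary residues even though
    # fragment-fragment pairs are later excluded as mutual neighbours
    by_group: dict[int, list[dict]] = {}
    for g in groups:
        ordinary = [s for s in sites if s["group"] == g and s["resname"] != "CRO"]
        fragments = [s for s in sites if s["group"] == g and s["resname"] == "CRO"]
        members = list(ordinary)
        for i, frag in enumerate(fragments):
            members.insert(min(2 + 2 * i, len(members)), frag)
        by_group[g] = members

    x_origin = 0.0
    prev_members: list[dict] | None = None
    bridge_atoms: list[tuple[int, int, np.ndarray]] = []  # (site, atom, pos)
    reach_slots: dict[int, int] = {}  # site index -> used reach atoms
    for g in groups:
        members = by_group[g]
        width = max(1, int(np.ceil(np.sqrt(len(members)))))
        for j, site in enumerate(members):
            row, col = divmod(j, width)
            if row % 2 == 1:
                col = width - 1 - col  # serpentine keeps neighbours adjacent
            site["center"] = np.array(
                [x_origin + lay.spacing * col, lay.spacing * row, 0.0]
            )
        if prev_members is not None:
            # bridge: reach atoms from the max-x site of the previous group
            # and a min-x, non-sequence-adjacent site of this group meet
            # halfway in the inter-group gap
            a_site = max(prev_members, key=lambda s: (s["center"][0], s["center"][1]))
            b_candidates = sorted(members, key=lambda s: (s["center"][0], s["center"][1]))
            # sequence-adjacent (and same-residue fragment) pairs are
            # neighbour-excluded downstream, which would disconnect the
            # graph -- pick the first candidate clear of the exclusion rule
            b_site = next(
                (s for s in b_candidates if abs(s["resid"] - a_site["resid"]) > 1),
                b_candidates[0],
            )
            y_mid = 0.5 * (a_site["center"][1] + b_site["center"][1])
            a_pos = np.array([a_site["center"][0] + lay.bridge_reach, y_mid, 0.0])
            b_pos = np.array([b_site["center"][0] - lay.bridge_reach, y_mid, 0.0])
            for site, pos in ((a_site, a_pos), (b_site, b_pos)):
                slot = reach_slots.get(site["index"], 0)
                atom = spec.atoms_per_residue - 1 - slot
                if atom < 1:
                    raise ValueError(
                        "not enough atoms per residue to place bridging atoms; "
                        "increase atoms_per_residue"
                    )
                reach_slots[site["index"]] = slot + 1
                bridge_atoms.append((site["index"], atom, pos))
        prev_members = members
        x_origin = max(s["center"][0] for s in members) + lay.group_gap

    # reference atom coordinates
    n_sites = len(sites)
    n_atoms = n_sites * spec.atoms_per_residue
    ref = np.empty((n_atoms, 3))
    meta_rows = []
    for s_i, site in enumerate(sites):
        for a in range(spec.atoms_per_residue):
            ref[s_i * spec.atoms_per_residue + a] = site["center"] + np.array(
                [0.0, 0.0, lay.atom_dz * a]
            )
            meta_rows.append(
                {
                    "name": site["atom_names"][a],
                    "residue_index": site["resid"],
                    "residue_name": site["resname"],
                    "chain": "A",
                }
            )
    for s_i, a, pos in bridge_atoms:
        ref[s_i * spec.atoms_per_residue + a] = pos

    # --- dynamics ---------------------------------------------------------
    n_groups = max(groups) + 1
    walks = {}
    raw = {g: np.cumsum(rng.standard_normal((spec.n_frames, 3)), axis=0) for g in groups}
    # orthogonalise the centred walks across groups (Gram-Schmidt on the
    # flattened series, norm preserved): independent random walks carry
    # large spurious cross-correlations, which would blur the planted
    # community structure the generator is supposed to define
    basis: list[np.ndarray] = []
    for g in groups:
        v = raw[g] - raw[g].mean(axis=0)
        u = v.ravel().copy()
        for b in basis:
            u -= (u @ b) * b
        norm = np.linalg.norm(u)
        if norm < 1e-12:  # pragma: no cover - degenerate draw
            raise RuntimeError("degenerate latent walks; change the seed")
        basis.append(u / norm)
        walks[g] = (u * (np.linalg.norm(v) / norm)).reshape(spec.n_frames, 3)
    coords = np.empty((spec.n_frames, n_atoms, 3))
    site_group = np.array([s["group"] for s in sites])
    atom_group = np.repeat(site_group, spec.atoms_per_residue)
    disp = np.zeros((spec.n_frames, n_atoms, 3))
    for g in groups:
        amp = _group_amplitude(spec, g, n_groups)
        disp[:, atom_group == g, :] = amp * walks[g][:, None, :]
    noise = (
        rng.standard_normal((spec.n_frames, n_atoms, 3)) * spec.noise_sigma
        if spec.noise_sigma > 0
        else 0.0
    )
    coords = ref[None, :, :] + disp + noise

    meta = pd.DataFrame(meta_rows)
    traj = Trajectory(coords=coords, atom_meta=meta)
    node_groups = {s["label"]: int(s["group"]) for s in sites}
    return PlantedTrajectory(
        trajectory=traj, node_groups=node_groups, chromophore_table=chromophore_table
    )


# --------------------------------------------------------------------------
# kinetics
# --------------------------------------------------------------------------


@dataclass
class KineticSpec:
    """Parameters of a mono-exponential switching trace I(t) = A·e^(−kt) + c."""

    A: float = 0.95
    k: float = 3.39  # s^-1
    c: float = 0.05
    dt: float = 0.05  # s
    n_points: int = 200
    noise_sigma: float = 0.005
    n_cycles: int = 1
    bleach_factor: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.A < 0 or self.c < 0:
            raise ValueError("A and c must be >= 0")
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.dt <= 0 or self.n_points < 1:
            raise ValueError("dt must be > 0 and n_points >= 1")
        if not (0.0 < self.bleach_factor <= 1.0):
            raise ValueError("bleach_factor must be in (0, 1]")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


@dataclass
class DecayTrace:
    t: np.ndarray  # s
    intensity: np.ndarray  # a.u.
    variant: str = ""
    form: str = "green"
    cycle: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.t.shape != self.intensity.shape:
            raise ValueError("t and intensity must have equal length")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")


def gen_decay_trace(
    spec: KineticSpec, rng: np.random.Generator | None = None
) -> DecayTrace:
    """One noisy mono-exponential decay trace."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_points) * spec.dt
    clean = spec.A * np.exp(-spec.k * t) + spec.c
    noise = rng.normal(0.0, spec.noise_sigma, spec.n_points) if spec.noise_sigma else 0.0
    return DecayTrace(t=t, intensity=clean + noise)


def gen_switch_cycles(spec: KineticSpec) -> list[DecayTrace]:
    """Repeated on–off cycles; cycle m keeps k and c but starts with
    amplitude A·bleach_factor^(m−1)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    traces = []
    for m in range(spec.n_cycles):
        cycle_spec = KineticSpec(
            A=spec.A * spec.bleach_factor**m,
            k=spec.k,
            c=spec.c,
            dt=spec.dt,
            n_points=spec.n_points,
            noise_sigma=spec.noise_sigma,
        )
        trace = gen_decay_trace(cycle_spec, rng=rng)
        trace.cycle = m
        traces.append(trace)
    return traces


# --------------------------------------------------------------------------
# titrations, BLA mixtures, paired spectra
# --------------------------------------------------------------------------


@dataclass
class TitrationCurve:
    ph: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.ph = np.asarray(self.ph, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.ph.shape != self.absorbance.shape:
            raise ValueError("pH and absorbance must have equal length")
        if self.ph.size >= 2 and not np.all(np.diff(self.ph) > 0):
            raise ValueError("pH grid must be strictly increasing")


def gen_titration(
    pka: float,
    a_max: float,
    ph_grid: Sequence[float],
    sigma: float = 0.0,
    seed: int = 0,
) -> TitrationCurve:
    """Single-site Henderson–Hasselbalch titration of the anionic band:
    A(pH) = a_max / (1 + 10^(pKa − pH)) + noise."""
    ph = np.asarray(list(ph_grid), dtype=float)
    if ph.size == 0:
        raise ValueError("ph_grid must be non-empty")
    if ph.size >= 2 and not np.all(np.diff(ph) > 0):
        raise ValueError("ph_grid must be strictly increasing")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    a = a_max / (1.0 + 10.0 ** (pka - ph))
    if sigma:
        a = a + rng.normal(0.0, sigma, ph.size)
    return TitrationCurve(ph=ph, absorbance=a)


def gen_bla_samples(
    weights: Sequence[float],
    means: Sequence[float],
    sds: Sequence[float],
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """i.i.d. draws (Å) from a 3-component Gaussian mixture of BLA values."""
    weights = np.asarray(list(weights), dtype=float)
    means = np.asarray(list(means), dtype=float)
    sds = np.asarray(list(sds), dtype=float)
    if not (weights.shape == means.shape == sds.shape):
        raise ValueError("weights, means and sds must have equal length")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    if np.any(weights < 0):
        raise ValueError("weights must be >= 0")
    if np.any(sds <= 0):
        raise ValueError("sds must be > 0")
    rng = np.random.default_rng(seed)
    comp = rng.choice(weights.size, size=n, p=weights)
    return rng.normal(means[comp], sds[comp])


@dataclass(frozen=True)
class SpectrumPair:
    """Paired band-maximum absorbance changes on illumination: the green
    band bleaches (delta_green < 0) while the red band grows."""

    delta_green: float
    delta_red: float

    def __post_init__(self) -> None:
        if self.delta_green >= 0:
            raise ValueError("delta_green must be < 0 (green band bleaches)")
        if self.delta_red < 0:
            raise ValueError("delta_red must be >= 0")


def gen_spectra_pair(delta_green: float, delta_red: float) -> SpectrumPair:
    return SpectrumPair(delta_green=delta_green, delta_red=delta_red)


# --------------------------------------------------------------------------
# writers
# --------------------------------------------------------------------------


def write_ground_truth(planted: PlantedTrajectory, path: str | Path) -> None:
    """TSV (node_id, community) of the planted partition."""
    rows = [
        {"node_id": label, "community": group}
        for label, group in planted.node_groups.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_trace_csv(trace: DecayTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.t, "intensity": trace.intensity}).to_csv(
        path, index=False
    )


def write_cycles_csv(traces: Sequence[DecayTrace], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {"time_s": tr.t, "intensity": tr.intensity, "cycle": tr.cycle}
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_titration_csv(curve: TitrationCurve, path: str | Path) -> None:
    pd.DataFrame({"pH": curve.ph, "absorbance": curve.absorbance}).to_csv(
        path, index=False
    )


def write_spec_json(spec, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(spec), fh, indent=2, default=lambda o: list(o))
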