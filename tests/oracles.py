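"""Independent reference implementations used only to check the package:
brute-force loops, exhaustive enumeration, quaternion superposition and
grid searches.  Nothing here is imported by the package itself."""

from __future__ import annotations

import itertools

import numpy as np
import networkx as nx


def brute_force_occupancy(coords, members, cutoff):
    """O(pairs * frames * atoms^2) python-loop contact occupancy."""
    n = len(members)
    frames = coords.shape[0]
    occ = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            hits = 0
            for f in range(frames):
                dmin = min(
                    float(np.linalg.norm(coords[f, a] - coords[f, b]))
                    for a in members[i]
                    for b in members[j]
                )
                if dmin < cutoff:
                    hits += 1
            occ[i, j] = hits / frames
    return occ


def direct_correlation(reps):
    """Loop evaluation of the DCCM formula on representative coordinates
    of shape (frames, nodes, 3)."""
    frames, n, _ = reps.shape
    mean = reps.mean(axis=0)
    c = np.eye(n)
    for i in range(n):
        for j in range(n):
            num = sum(
                float(np.dot(reps[f, i] - mean[i], reps[f, j] - mean[j]))
                for f in range(frames)
            )
            vi = sum(float(np.dot(reps[f, i] - mean[i], reps[f, i] - mean[i])) for f in range(frames))
            vj = sum(float(np.dot(reps[f, j] - mean[j], reps[f, j] - mean[j])) for f in range(frames))
            c[i, j] = num / np.sqrt(vi * vj)
    return c


def set_partitions(items):
    """All set partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def exhaustive_best_modularity(graph: nx.Graph) -> float:
    """Maximum Newman-Girvan modularity (strength-weighted) over every
    partition of the node set.  Feasible up to ~9 nodes."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((n, n))
    for i, j, d in graph.edges(data=True):
        a[index[i], index[j]] = d["strength"]
        a[index[j], index[i]] = d["strength"]
    k = a.sum(axis=1)
    m2 = a.sum()
    b = a - np.outer(k, k) / m2
    best = -np.inf
    for part in set_partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for c, mem in enumerate(part):
            labels[mem] = c
        same = labels[:, None] == labels[None, :]
        best = max(best, float((b * same).sum() / m2))
    return best


def two_block_toy(seed: int, n: int) -> nx.Graph:
    """Seeded weighted toy graph with two planted blocks and one or two
    weak cross edges; edge attributes match the package's convention."""
    rng = np.random.default_rng(seed)
    split = n // 2
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for block in (range(split), range(split, n)):
        for i, j in itertools.combinations(block, 2):
            s = rng.uniform(0.6, 0.95)
            g.add_edge(i, j, strength=s, weight=float(-np.log(s)))
    for _ in range(int(rng.integers(1, 3))):
        i = int(rng.integers(0, split))
        j = int(rng.integers(split, n))
        s = rng.uniform(0.05, 0.3)
        g.add_edge(i, j, strength=s, weight=float(-np.log(s)))
    return g


def quaternion_min_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD over rigid-body motions via Horn's quaternion method."""
    p = mobile - mobile.mean(axis=0)
    q = reference - reference.mean(axis=0)
    m = p.T @ q
    k = np.array(
        [
            [m[0, 0] + m[1, 1] + m[2, 2], m[1, 2] - m[2, 1], m[2, 0] - m[0, 2], m[0, 1] - m[1, 0]],
            [m[1, 2] - m[2, 1], m[0, 0] - m[1, 1] - m[2, 2], m[0, 1] + m[1, 0], m[2, 0] + m[0, 2]],
            [m[2, 0] - m[0, 2], m[0, 1] + m[1, 0], -m[0, 0] + m[1, 1] - m[2, 2], m[1, 2] + m[2, 1]],
            [m[0, 1] - m[1, 0], m[2, 0] + m[0, 2], m[1, 2] + m[2, 1], -m[0, 0] - m[1, 1] + m[2, 2]],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    n = p.shape[0]
    msd = max((np.sum(p**2) + np.sum(q**2) - 2.0 * lam) / n, 0.0)
    return float(np.sqrt(msd))


def grid_search_monoexp(t, intensity, a_range, k_range, c_range, steps=40):
    """Coarse brute-force least squares over the (A, k, c) grid."""
    best = (np.inf, None)
    for a in np.linspace(*a_range, steps):
        for k in np.linspace(*k_range, steps):
            for c in np.linspace(*c_range, steps):
                sse = float(np.sum((a * np.exp(-k * t) + c - intensity) ** 2))
                if sse < best[0]:
                    best = (sse, (a, k, c))
    return best[1]


def grid_search_pka(ph, absorbance, lo=4.0, hi=10.0, step=0.002):
    """Profile out a_max in closed form, grid-search pKa."""
    best = (np.inf, None)
    for pka in np.arange(lo, hi + step, step):
        f = 1.0 / (1.0 + 10.0 ** (pka - ph))
        a_max = float(np.dot(f, absorbance) / np.dot(f, f))
        sse = float(np.sum((a_max * f - absorbance) ** 2))
        if sse < best[0]:
            best = (sse, pka)
    return best[1]
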