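"""Bond-length alternation (BLA) of the chromophore methine bridge and its
three-Gaussian mixture decomposition.

BLA is the difference between the two C–C bond lengths of the C–C=C bridge,
``d(C_imid, C_bridge) − d(C_bridge, C_phenol)``; the sign convention makes
the phenolic-predominant resonance form positive.  The per-frame BLA
distribution is decomposed into three Gaussian components by EM; the
right-most component (largest mean) tracks the fraction associated with
shorter absorption wavelengths and more facile cis–trans isomerisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajio import Trajectory

__all__ = [
    "BlaSeries",
    "GmmFit",
    "compute_bla",
    "fit_gmm3",
    "rightmost_component",
]


@dataclass
class BlaSeries:
    values: np.ndarray  # Å, one per frame
    triplet: tuple[str, str, str]  # (C_imid-side, C_bridge, C_phenol-side)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class GmmFit:
    """Three-component 1-D Gaussian mixture, components sorted by mean."""

    weights: np.ndarray
    means: np.ndarray  # Å
    sds: np.ndarray  # Å
    log_likelihood: float

    def __post_init__(self) -> None:
        order = np.argsort(self.means)
        self.weights = np.asarray(self.weights, dtype=float)[order]
        self.means = np.asarray(self.means, dtype=float)[order]
        self.sds = np.asarray(self.sds, dtype=float)[order]


def _atom_index(traj: Trajectory, name: str) -> int:
    idx = np.flatnonzero(traj.atom_meta["name"].to_numpy() == name)
    if idx.size == 0:
        raise ValueError(f"atom '{name}' not found in trajectory")
    if idx.size > 1:
        raise ValueError(f"atom name '{name}' is ambiguous ({idx.size} matches)")
    return int(idx[0])


def compute_bla(traj: Trajectory, triplet: tuple[str, str, str]) -> BlaSeries:
    """Per-frame BLA = d(imid-side C, bridge C) − d(bridge C, phenol-side C)."""
    if len(triplet) != 3:
        raise ValueError("triplet must name exactly three atoms")
    a, b, c = (_atom_index(traj, name) for name in triplet)
    d_ab = np.linalg.norm(traj.coords[:, a] - traj.coords[:, b], axis=1)
    d_bc = np.linalg.norm(traj.coords[:, b] - traj.coords[:, c], axis=1)
    return BlaSeries(values=d_ab - d_bc, triplet=tuple(triplet))


def fit_gmm3(
    samples: np.ndarray, n_restarts: int = 5, seed: int = 0
) -> GmmFit:
    """Three-Gaussian EM decomposition of a 1-D sample.

    EM runs to convergence (mean log-likelihood change < 1e-8, up to 500
    iterations); the best of ``n_restarts`` initialisations is kept.  The
    first initialisation places the means at the 1/6, 1/2 and 5/6 sample
    quantiles; later restarts perturb those means with seeded noise.
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 30:
        raise ValueError(f"need at least 30 samples for a 3-component fit, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: all values identical")
    rng = np.random.default_rng(seed)
    base_means = np.quantile(x, [1 / 6, 1 / 2, 5 / 6])
    scale = max(x.std(), 1e-12)

    best = None
    for restart in range(max(1, n_restarts)):
        means = base_means.copy()
        if restart > 0:
            means = means + rng.normal(0.0, 0.25 * scale, 3)
        gm = GaussianMixture(
            n_components=3,
            covariance_type="full",
            tol=1e-8,
            max_iter=500,
            means_init=means.reshape(-1, 1),
            weights_init=np.full(3, 1 / 3),
            precisions_init=np.full((3, 1, 1), 1.0 / (0.5 * scale) ** 2),
            random_state=int(rng.integers(2**31 - 1)),
        )
        gm.fit(x.reshape(-1, 1))
        if best is None or gm.lower_bound_ > best.lower_bound_:
            best = gm

    weights = best.weights_
    means = best.means_.ravel()
    sds = np.sqrt(best.covariances_.ravel())
    return GmmFit(
        weights=weights,
        means=means,
        sds=sds,
        log_likelihood=float(best.lower_bound_ * x.size),
    )


def rightmost_component(fit: GmmFit) -> tuple[float, float]:
    """(weight, mean) of the component with the largest mean; a tie in
    means goes to the larger-weight component."""
    max_mean = fit.means.max()
    tied = np.flatnonzero(np.isclose(fit.means, max_mean))
    pick = tied[np.argmax(fit.weights[tied])]
    return float(fit.weights[pick]), float(fit.means[pick])
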