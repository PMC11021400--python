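"""Spectroscopic estimators: chromophore pKa, red-form extinction
coefficient, and relative fluorescence quantum yield.

* pKa comes from a single-site Henderson–Hasselbalch fit of the anionic
  absorption band against pH, A(pH) = A_an / (1 + 10^(pKa − pH)).
* The red-form extinction coefficient follows the paired-absorbance rule:
  when green chromophore is photoconverted to red with negligible
  photodestruction, every lost green absorber becomes a red absorber, so
  ε_R = (ΔA_R / |ΔA_G|) · ε_G.
* Relative quantum yield is the ratio of the slopes of integrated
  fluorescence against absorbance over a dilution series, scaled by the
  reference fluorophore's quantum yield.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .synthgen import SpectrumPair, TitrationCurve

__all__ = [
    "PkaFit",
    "fit_pka",
    "epsilon_red",
    "relative_qy",
]


@dataclass
class PkaFit:
    pka: float
    pka_err: float
    a_max: float
    baseline: float
    residual_rms: float


def fit_pka(curve: TitrationCurve, with_baseline: bool = False) -> PkaFit:
    """Least-squares Henderson–Hasselbalch fit of a titration curve.

    ``with_baseline`` adds a pH-independent acid-limb offset.  Raises if
    the curve shows no protonation transition inside the measured pH range.
    """
    import lmfit

    ph = curve.ph
    a = curve.absorbance
    if ph.size < 5:
        raise ValueError("need at least 5 titration points")
    amax0 = float(a.max())
    if amax0 <= 0 or (a.max() - a.min()) < 0.1 * max(abs(a.max()), 1e-12):
        raise ValueError("no protonation transition within the pH range")
    half = a.min() + 0.5 * (a.max() - a.min())
    pka0 = float(ph[np.argmin(np.abs(a - half))])

    def model_fn(ph, pka, a_max, a0):
        return a0 + a_max / (1.0 + 10.0 ** (pka - ph))

    model = lmfit.Model(model_fn)
    params = model.make_params(
        pka=dict(value=pka0),
        a_max=dict(value=amax0, min=0.0),
        a0=dict(value=0.0, vary=with_baseline),
    )
    result = model.fit(a, params, ph=ph)
    if not result.success:
        raise RuntimeError(f"pKa fit did not converge: {result.message}")
    pka = float(result.params["pka"].value)
    if not (ph.min() - 1.0 <= pka <= ph.max() + 1.0):
        raise ValueError(
            f"fitted pKa {pka:.2f} lies outside the measured pH range "
            f"[{ph.min()}, {ph.max()}]"
        )
    return PkaFit(
        pka=pka,
        pka_err=float(result.params["pka"].stderr or np.nan),
        a_max=float(result.params["a_max"].value),
        baseline=float(result.params["a0"].value),
        residual_rms=float(np.sqrt(np.mean(result.residual**2))),
    )


def epsilon_red(pair: SpectrumPair, eps_green: float) -> float:
    """Red-form extinction coefficient from paired absorbance changes:
    ε_R = (ΔA_R / |ΔA_G|) · ε_G."""
    if eps_green <= 0:
        raise ValueError("eps_green must be positive")
    if pair.delta_green >= 0:
        raise ValueError("delta_green must be negative")
    return (pair.delta_red / abs(pair.delta_green)) * eps_green


def _slope_through_origin(x: np.ndarray, y: np.ndarray) -> float:
    denom = float(np.dot(x, x))
    if denom == 0:
        raise ValueError("all-zero absorbance values")
    return float(np.dot(x, y)) / denom


def relative_qy(
    sample_absorbance: Sequence[float],
    sample_area: Sequence[float],
    ref_absorbance: Sequence[float],
    ref_area: Sequence[float],
    phi_ref: float,
) -> float:
    """Relative quantum yield from dilution series.

    φ = φ_ref · slope(area vs A)_sample / slope(area vs A)_ref, with
    through-origin least-squares slopes (zero absorbance implies zero
    emission).  Dilutions should keep absorbance at or below 0.1 so that
    inner-filter effects stay negligible.
    """
    xs = np.asarray(list(sample_absorbance), dtype=float)
    ys = np.asarray(list(sample_area), dtype=float)
    xr = np.asarray(list(ref_absorbance), dtype=float)
    yr = np.asarray(list(ref_area), dtype=float)
    if xs.size < 3 or xr.size < 3:
        raise ValueError("need at least 3 dilutions per series")
    if xs.shape != ys.shape or xr.shape != yr.shape:
        raise ValueError("absorbance/area series must have equal length")
    if np.any(xs > 0.1 + 1e-12) or np.any(xr > 0.1 + 1e-12):
        import warnings

        warnings.warn(
            "absorbance exceeds 0.1; inner-filter effects may bias the slope",
            stacklevel=2,
        )
    slope_ref = _slope_through_origin(xr, yr)
    if slope_ref <= 0:
        raise ValueError("reference slope must be positive")
    slope_sample = _slope_through_origin(xs, ys)
    return phi_ref * slope_sample / slope_ref
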