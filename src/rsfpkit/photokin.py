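"""On-to-off photoswitching kinetics.

Fluorescence decay during off-switching follows a mono-exponential law,
I(t) = A·exp(−k·t) + c, with k the off-switching rate constant (k_off),
A the switchable amplitude and c the non-switching plateau.  From the fit
this module derives the switching contrast SC = 100·A/(A+c) (the percent
drop from the fitted initial intensity to the plateau), fold-changes of
k_off between variants, and the per-cycle photostability (geometric loss
factor of the initial intensity over repeated switching cycles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthgen import DecayTrace

__all__ = [
    "MonoExpFit",
    "CycleStability",
    "fit_monoexp",
    "switching_contrast",
    "rate_fold_change",
    "cycle_photostability",
    "normalize_trace",
]


@dataclass
class MonoExpFit:
    A: float
    k: float  # s^-1
    c: float
    A_err: float
    k_err: float
    c_err: float
    residual_rms: float

    def initial_intensity(self) -> float:
        return self.A + self.c


def normalize_trace(trace: DecayTrace) -> DecayTrace:
    """Normalise to the initial intensity (first sample = 1)."""
    i0 = trace.intensity[0]
    if i0 <= 0:
        raise ValueError("cannot normalise: first sample is non-positive")
    return DecayTrace(
        t=trace.t,
        intensity=trace.intensity / i0,
        variant=trace.variant,
        form=trace.form,
        cycle=trace.cycle,
    )


def _initial_guess(t: np.ndarray, intensity: np.ndarray) -> tuple[float, float, float]:
    c0 = float(intensity.min())
    y = intensity - c0
    pos = y > 0
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
        k0 = -float(slope)
    else:
        k0 = 0.0
    a0 = float(intensity[0] - c0)
    return a0, k0, c0


def fit_monoexp(trace: DecayTrace) -> MonoExpFit:
    """Nonlinear least-squares fit of I(t) = A·exp(−k·t) + c.

    Initialisation: c0 = min(I), k0 from a log-linear regression of I − c0
    against t, A0 = I(0) − c0.  Traces that do not decay are rejected; the
    fit is also checked post hoc for covering at least one decay time 1/k.
    """
    import lmfit

    t = trace.t
    intensity = trace.intensity
    if t.size < 5:
        raise ValueError("need at least 5 points to fit a mono-exponential")
    a0, k0, c0 = _initial_guess(t, intensity)
    head = intensity[: max(2, t.size // 10)].mean()
    tail = intensity[-max(2, t.size // 10):].mean()
    if k0 <= 0 or tail >= head:
        raise ValueError("trace does not decay; mono-exponential fit rejected")

    model = lmfit.Model(lambda t, A, k, c: A * np.exp(-k * t) + c)
    params = model.make_params(
        A=dict(value=max(a0, 1e-9), min=0.0),
        k=dict(value=max(k0, 1e-9), min=1e-12),
        c=dict(value=c0),
    )
    result = model.fit(intensity, params, t=t)
    if not result.success:
        raise RuntimeError(f"mono-exponential fit did not converge: {result.message}")
    p = result.params
    k = float(p["k"].value)
    span = t[-1] - t[0]
    if span * k < 1.0:
        warnings.warn(
            f"trace spans only {span * k:.2f} decay times (1/k); "
            "the rate estimate may be poorly constrained",
            stacklevel=2,
        )
    residual_rms = float(np.sqrt(np.mean(result.residual**2)))
    return MonoExpFit(
        A=float(p["A"].value),
        k=k,
        c=float(p["c"].value),
        A_err=float(p["A"].stderr or np.nan),
        k_err=float(p["k"].stderr or np.nan),
        c_err=float(p["c"].stderr or np.nan),
        residual_rms=residual_rms,
    )


def switching_contrast(fit: MonoExpFit) -> float:
    """Switching contrast in percent: SC = 100·A/(A+c)."""
    total = fit.A + fit.c
    if total <= 0:
        raise ValueError("A + c must be positive to define a switching contrast")
    return 100.0 * fit.A / total


def rate_fold_change(fit_a: MonoExpFit, fit_b: MonoExpFit) -> tuple[float, float]:
    """k_a / k_b with the propagated relative standard error."""
    if fit_b.k <= 0:
        raise ValueError("reference rate must be positive")
    ratio = fit_a.k / fit_b.k
    rel = 0.0
    for fit in (fit_a, fit_b):
        if np.isfinite(fit.k_err):
            rel += (fit.k_err / fit.k) ** 2
    return ratio, ratio * float(np.sqrt(rel))


@dataclass
class CycleStability:
    initial_intensities: list[float]  # fitted A_m + c_m per cycle
    loss_factor: float  # per-cycle multiplicative loss
    fits: list[MonoExpFit | None]
    failed_cycles: list[int]


def cycle_photostability(traces: list[DecayTrace]) -> CycleStability:
    """Per-cycle initial intensities and the geometric loss factor.

    Each cycle is fitted separately; log(A_m + c_m) is regressed on the
    cycle index and the loss factor is exp(slope).  Cycles whose fit fails
    are flagged and excluded from the regression.
    """
    if len(traces) < 2:
        raise ValueError("need at least 2 cycles to estimate photostability")
    fits: list[MonoExpFit | None] = []
    failed: list[int] = []
    for m, trace in enumerate(traces):
        try:
            fits.append(fit_monoexp(trace))
        except (ValueError, RuntimeError):
            fits.append(None)
            failed.append(m)
    usable = [(m, f.initial_intensity()) for m, f in enumerate(fits) if f is not None]
    if len(usable) < 2:
        raise RuntimeError(
            f"photostability needs >= 2 fitted cycles; failures in cycles {failed}"
        )
    idx = np.array([m for m, _ in usable], dtype=float)
    i0 = np.array([v for _, v in usable])
    if np.any(i0 <= 0):
        raise RuntimeError("non-positive fitted initial intensity")
    slope = np.polyfit(idx, np.log(i0), 1)[0]
    return CycleStability(
        initial_intensities=[f.initial_intensity() if f else np.nan for f in fits],
        loss_factor=float(np.exp(slope)),
        fits=fits,
        failed_cycles=failed,
    )
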