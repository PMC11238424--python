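"""Differential variance analysis (DVA).

Structural relaxation is read directly off the images: the variance of the
intensity difference ΔI(r, t, Δt) = I(r, t+Δt) − I(r, t) grows from 0 (frozen
scene) to twice the static intensity variance (fully decorrelated scene).
The overlap function

    Q(Δt) = 1 − V(Δt) / V(∞),
    V(Δt) = ⟨ΔI(r, t, Δt)²⟩_{r,t},   V(∞) = 2 Var_{r,t}[I],

is an image-based proxy for the fraction of material that has not moved over
the lag, and behaves like the self-intermediate scattering function of
glass physics. Dynamic heterogeneity is quantified by the susceptibility

    χ4Q(Δt) = φ [⟨Q(t, Δt)²⟩_t − ⟨Q(t, Δt)⟩_t²],

the variance over reference times of the instantaneous overlap, scaled by
the area fraction φ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stack import ImageStack

__all__ = [
    "RelaxationCurve",
    "SusceptibilityCurve",
    "intensity_difference",
    "variance_curve",
    "overlap_function",
    "chi4_overlap",
    "default_lag_grid",
]


@dataclass
class RelaxationCurve:
    """A correlation value per lag time, with per-reference-time samples.

    ``per_t_samples[i]`` holds the instantaneous correlator (Q(t, Δt) or
    Cθ(t, Δt)) for every admissible reference time at ``lags[i]``; its mean
    equals ``values[i]`` up to rounding. The samples are what χ4 needs.
    """

    lags: np.ndarray  # seconds, strictly increasing
    values: np.ndarray
    per_t_samples: list[np.ndarray]
    n_ref: np.ndarray  # reference-time count per lag
    kind: str = "Q"  # "Q" (overlap) or "Ctheta"
    v_inf: float = np.nan  # only meaningful for overlap curves

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, float)
        self.values = np.asarray(self.values, float)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if len(self.lags) != len(self.values):
            raise ValueError("lags and values must align")


@dataclass
class SusceptibilityCurve:
    """χ4 per lag: area fraction × variance of the instantaneous correlator."""

    lags: np.ndarray
    chi4: np.ndarray
    phi_prefactor: float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.chi4) < -1e-15):
            raise ValueError("chi4 is a scaled variance and cannot be negative")


def default_lag_grid(n_frames: int, max_lag: int | None = None) -> np.ndarray:
    """Pseudo-logarithmic lag grid in frames: 1, 2, 3, 4, 6, 8, 11, 16, ...

    Capped at ``n_frames // 2`` (relaxation beyond half the window is not
    reliably sampled), or at ``max_lag`` if given.
    """
    cap = n_frames // 2 if max_lag is None else min(max_lag, n_frames - 1)
    if cap < 1:
        raise ValueError("stack too short for any lag")
    lags = []
    x = 1.0
    while round(x) <= cap:
        lag = int(round(x))
        if not lags or lag > lags[-1]:
            lags.append(lag)
        x *= np.sqrt(2)
    return np.array(lags, dtype=int)


def intensity_difference(stack: ImageStack, t_index: int, lag_frames: int) -> np.ndarray:
    """Signed pixel-wise difference I(t + Δt) − I(t) in float64."""
    if lag_frames < 1 or t_index < 0 or t_index + lag_frames >= stack.n_frames:
        raise IndexError(
            f"reference {t_index} + lag {lag_frames} outside stack of "
            f"{stack.n_frames} frames"
        )
    f = stack.frames
    return f[t_index + lag_frames].astype(np.float64) - f[t_index].astype(np.float64)


def variance_curve(
    stack: ImageStack, lags: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """V(Δt) = ⟨ΔI²⟩ over pixels and all admissible reference frames.

    Returns ``(lags_frames, V, V_inf)`` with V(∞) evaluated as twice the
    variance of the intensity pooled over every pixel and frame of the
    stack. All admissible (overlapping) reference times contribute.
    """
    if stack.n_frames < 2:
        raise ValueError("need at least two frames")
    if lags is None:
        lags = default_lag_grid(stack.n_frames)
    lags = np.asarray(lags, dtype=int)
    if np.any(lags < 1) or np.any(lags >= stack.n_frames):
        raise ValueError("every lag must satisfy 1 <= lag < n_frames")
    f = stack.frames.astype(np.float64)
    v = np.empty(len(lags))
    for i, lag in enumerate(lags):
        d = f[lag:] - f[:-lag]
        v[i] = np.mean(d * d)
    v_inf = 2.0 * float(np.var(f))
    return lags, v, v_inf


def overlap_function(
    stack: ImageStack, lags: np.ndarray | None = None
) -> RelaxationCurve:
    """Overlap Q(Δt) = 1 − V(Δt)/V(∞), with per-reference-time samples."""
    if stack.n_frames < 2:
        raise ValueError("need at least two frames")
    if lags is None:
        lags = default_lag_grid(stack.n_frames)
    lags = np.asarray(lags, dtype=int)
    f = stack.frames.astype(np.float64)
    v_inf = 2.0 * float(np.var(f))
    if v_inf <= 0:
        raise ValueError("V(inf) = 0: constant stack, overlap undefined")
    values = np.empty(len(lags))
    samples: list[np.ndarray] = []
    for i, lag in enumerate(lags):
        d = f[lag:] - f[:-lag]
        per_t = 1.0 - np.mean(d * d, axis=(1, 2)) / v_inf
        samples.append(per_t)
        values[i] = per_t.mean()
    return RelaxationCurve(
        lags=lags * stack.frame_interval,
        values=values,
        per_t_samples=samples,
        n_ref=np.array([len(s) for s in samples]),
        kind="Q",
        v_inf=v_inf,
    )


def chi4_overlap(curve: RelaxationCurve, phi: float) -> SusceptibilityCurve:
    """χ4(Δt) = φ × Var_t[instantaneous correlator at lag Δt].

    The variance is the population variance over reference times (the
    plain ⟨x²⟩ − ⟨x⟩² of the definition). Needs ≥ 2 reference times per lag.
    """
    chi4 = np.empty(len(curve.lags))
    for i, s in enumerate(curve.per_t_samples):
        if len(s) < 2:
            raise ValueError(
                f"lag {curve.lags[i]:g}s has a single reference time; "
                "variance undefined"
            )
        chi4[i] = phi * np.var(s)
    return SusceptibilityCurve(lags=curve.lags.copy(), chi4=chi4, phi_prefactor=phi)
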