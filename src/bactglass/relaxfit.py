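"""Relaxation-curve and relaxation-time-law fitting.

Three laws cover the slowdown phenomenology of a glass former approaching
its transition:

* stretched exponential, Q(Δt) = a·exp[−(Δt/τ)^β] — the α-relaxation of a
  single curve, yielding the relaxation time τ and stretching exponent β;
* mode-coupling power law, τ(φ) = a·(φc − φ)^(−γ) — divergence of τ at a
  critical area fraction φc;
* Vogel–Fulcher–Tammann law, τ(φ) = A·exp[c·φ/(φ_VFT − φ)] — the
  super-exponential alternative characteristic of fragile glass formers.

Law fits are performed on log τ (τ spans decades; log space weights the
decades evenly). All fits use damped Gauss–Newton (trust-region) least
squares with deterministic multi-starts, and report 95% confidence
intervals from the linearized covariance.

The module also provides the thermal MCT exponent bound: the exponent
relations λ = Γ(1−a)²/Γ(1−2a) = Γ(1+b)²/Γ(1+2b), γ = 1/(2a) + 1/(2b)
constrain γ ≥ γ_min ≈ 1.765 for thermal systems, the minimum being attained
at λ = 1/2 where b = 1. A measured γ below this bound signals athermal
(active) dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .dva import RelaxationCurve

__all__ = [
    "StretchedExpFit",
    "MCTFit",
    "VFTFit",
    "MCTExponentBound",
    "fit_stretched_exponential",
    "fit_mct",
    "fit_vft",
    "mct_thermal_gamma_min",
    "gamma_of_lambda",
]


def _ci_from_lsq(res, dof_total: int) -> np.ndarray:
    """95% CIs from the linearized covariance of a least_squares result."""
    n_par = len(res.x)
    dof = dof_total - n_par
    J = res.jac
    s2 = 2 * res.cost / dof if dof > 0 else np.nan
    try:
        cov = np.linalg.inv(J.T @ J) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(n_par, np.nan)
    tval = stats.t.ppf(0.975, dof) if dof > 0 else np.inf
    return tval * se


@dataclass
class StretchedExpFit:
    tau: float  # relaxation time, s
    tau_ci: tuple[float, float]
    beta: float  # stretching exponent
    beta_ci: tuple[float, float]
    amplitude: float
    residual_norm: float
    censored: bool = False  # True: curve never decayed below a/e; tau is a lower bound


def fit_stretched_exponential(
    curve: RelaxationCurve | tuple[np.ndarray, np.ndarray],
    fit_range: tuple[float, float] | None = None,
    allow_censored: bool = False,
) -> StretchedExpFit:
    """Fit a·exp[−(Δt/τ)^β] to a relaxation curve.

    Deterministic multi-start over β ∈ {0.5, 1.0, 1.5}; amplitude bounded in
    (0, 1.5]. If the curve never decays below a/e of its initial plateau
    within the (optionally restricted) window, the relaxation time is not
    identified: an error is raised unless ``allow_censored``, in which case
    the extrapolated τ is returned flagged as a lower bound.
    """
    if isinstance(curve, RelaxationCurve):
        t, y = curve.lags, curve.values
    else:
        t, y = (np.asarray(v, float) for v in curve)
    if fit_range is not None:
        sel = (t >= fit_range[0]) & (t <= fit_range[1])
        t, y = t[sel], y[sel]
    if len(t) < 5:
        raise ValueError("need at least 5 points to fit")
    a0 = y[0]
    decayed = np.any(y < a0 / np.e)
    if not decayed and not allow_censored:
        raise ValueError("relaxation not observed within window")

    def resid(p):
        a, log_tau, beta = p
        return a * np.exp(-((t / np.exp(log_tau)) ** beta)) - y

    best = None
    t_scale = t[max(1, len(t) // 2)]
    for beta0 in (0.5, 1.0, 1.5):
        res = optimize.least_squares(
            resid,
            x0=[min(max(a0, 1e-3), 1.5), np.log(t_scale), beta0],
            bounds=([1e-6, np.log(t[0]) - 20, 1e-3], [1.5, np.log(t[-1]) + 20, 2.0]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        if best is None or res.cost < best.cost:
            best = res
    a, log_tau, beta = best.x
    ci = _ci_from_lsq(best, len(t))
    tau = float(np.exp(log_tau))
    hw = min(ci[1], 700.0)  # exp() overflow guard for unidentified fits
    # delta method: CI on log tau maps multiplicatively to tau
    return StretchedExpFit(
        tau=tau,
        tau_ci=(tau * float(np.exp(-hw)), tau * float(np.exp(hw))),
        beta=float(beta),
        beta_ci=(float(beta - ci[2]), float(beta + ci[2])),
        amplitude=float(a),
        residual_norm=float(np.sqrt(2 * best.cost)),
        censored=not decayed,
    )


@dataclass
class MCTFit:
    phi_c: float
    phi_c_ci: tuple[float, float]
    gamma: float
    gamma_ci: tuple[float, float]
    amplitude: float
    residual_norm: float


def _check_law_inputs(phis, taus):
    phis = np.asarray(phis, float)
    taus = np.asarray(taus, float)
    if len(phis) < 4:
        raise ValueError("need at least 4 (phi, tau) pairs")
    order = np.argsort(phis)
    phis, taus = phis[order], taus[order]
    if np.any(np.diff(taus) < 0):
        warnings.warn(
            "tau(phi) is not monotonically increasing; fit proceeds",
            RuntimeWarning,
        )
    return phis, taus


def fit_mct(phis: np.ndarray, taus: np.ndarray) -> MCTFit:
    """Fit the mode-coupling power law τ = a (φc − φ)^(−γ) in log-τ space.

    φc is a free nonlinear parameter bounded below by the largest observed
    φ; deterministic multi-start over the initial offset of φc above it.
    """
    phis, taus = _check_law_inputs(phis, taus)
    log_tau = np.log(taus)
    phi_max = phis.max()

    def resid(p):
        log_a, gamma, phi_c = p
        return log_a - gamma * np.log(phi_c - phis) - log_tau

    best = None
    for dphi in (0.005, 0.02, 0.05, 0.15):
        res = optimize.least_squares(
            resid,
            x0=[np.mean(log_tau), 2.0, phi_max + dphi],
            bounds=([-50, 1e-3, phi_max + 1e-9], [50, 50, 2.0]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        if best is None or res.cost < best.cost:
            best = res
    log_a, gamma, phi_c = best.x
    ci = _ci_from_lsq(best, len(phis))
    return MCTFit(
        phi_c=float(phi_c),
        phi_c_ci=(float(phi_c - ci[2]), float(phi_c + ci[2])),
        gamma=float(gamma),
        gamma_ci=(float(gamma - ci[1]), float(gamma + ci[1])),
        amplitude=float(np.exp(log_a)),
        residual_norm=float(np.sqrt(2 * best.cost)),
    )


@dataclass
class VFTFit:
    phi_vft: float
    phi_vft_ci: tuple[float, float]
    c: float
    c_ci: tuple[float, float]
    amplitude: float
    residual_norm: float
    variant: str = "phi"  # "phi": exp(c phi/(phi_vft-phi)); "plain": exp(c/(phi_vft-phi))


def fit_vft(phis: np.ndarray, taus: np.ndarray, variant: str = "phi") -> VFTFit:
    """Fit the VFT law τ = A exp[c φ/(φ_VFT − φ)] in log-τ space.

    ``variant="plain"`` drops the φ in the numerator, τ = A exp[c/(φ_VFT − φ)]
    (both parameterizations circulate in the literature).
    """
    if variant not in ("phi", "plain"):
        raise ValueError("variant must be 'phi' or 'plain'")
    phis, taus = _check_law_inputs(phis, taus)
    log_tau = np.log(taus)
    phi_max = phis.max()
    numer = phis if variant == "phi" else 1.0

    def resid(p):
        log_A, c, phi_vft = p
        return log_A + c * numer / (phi_vft - phis) - log_tau

    best = None
    for dphi in (0.005, 0.02, 0.05, 0.15):
        res = optimize.least_squares(
            resid,
            x0=[log_tau.min(), 1.0, phi_max + dphi],
            bounds=([-50, 1e-6, phi_max + 1e-9], [50, 100, 3.0]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        if best is None or res.cost < best.cost:
            best = res
    log_A, c, phi_vft = best.x
    ci = _ci_from_lsq(best, len(phis))
    return VFTFit(
        phi_vft=float(phi_vft),
        phi_vft_ci=(float(phi_vft - ci[2]), float(phi_vft + ci[2])),
        c=float(c),
        c_ci=(float(c - ci[1]), float(c + ci[1])),
        amplitude=float(np.exp(log_A)),
        residual_norm=float(np.sqrt(2 * best.cost)),
        variant=variant,
    )


# ---------------------------------------------------------------------------
# MCT exponent relations


def _lambda_of_a(a):
    return special.gamma(1 - a) ** 2 / special.gamma(1 - 2 * a)


def _lambda_of_b(b):
    return special.gamma(1 + b) ** 2 / special.gamma(1 + 2 * b)


def _solve_a(lam: float) -> float:
    """a ∈ (0, 1/2) with Γ(1−a)²/Γ(1−2a) = λ (monotone decreasing in a)."""
    return optimize.brentq(
        lambda a: _lambda_of_a(a) - lam, 1e-12, 0.5 - 1e-12, xtol=1e-14
    )


def _solve_b(lam: float) -> float:
    """b > 0 with Γ(1+b)²/Γ(1+2b) = λ (monotone decreasing in b)."""
    return optimize.brentq(
        lambda b: _lambda_of_b(b) - lam, 1e-12, 1.0 + 1e-9, xtol=1e-14
    )


def gamma_of_lambda(lam) -> np.ndarray:
    """MCT exponent γ(λ) = 1/(2a) + 1/(2b) on λ ∈ [1/2, 1)."""
    lam = np.atleast_1d(np.asarray(lam, float))
    if np.any(lam < 0.5) or np.any(lam >= 1.0):
        raise ValueError("exponent parameter lambda must lie in [0.5, 1)")
    out = np.empty_like(lam)
    for i, l in enumerate(lam):
        a = _solve_a(l)
        b = _solve_b(l)
        out[i] = 0.5 / a + 0.5 / b
    return out


@dataclass
class MCTExponentBound:
    gamma_min: float
    a: float  # critical-decay exponent at the minimum
    b: float  # von Schweidler exponent at the minimum (= 1)
    lam: float  # exponent parameter at the minimum (= 1/2)
    grid_lam: np.ndarray = field(repr=False, default=None)
    grid_gamma: np.ndarray = field(repr=False, default=None)


def mct_thermal_gamma_min(n_grid: int = 101) -> MCTExponentBound:
    """Smallest power-law exponent γ compatible with thermal MCT.

    Solves the exponent relations at the boundary λ = 1/2 of the admissible
    range (where b = 1 exactly, since Γ(2)²/Γ(3) = 1/2), giving
    γ_min = 1/(2a) + 1/2 ≈ 1.765. A γ(λ) grid on [1/2, 1) is attached;
    γ is increasing in λ, confirming the boundary value is the minimum.
    """
    lam0 = 0.5
    a = _solve_a(lam0)
    b = 1.0
    gamma_min = 0.5 / a + 0.5 / b
    lam_grid = np.linspace(0.5, 1.0 - 1e-6, n_grid)
    return MCTExponentBound(
        gamma_min=float(gamma_min),
        a=float(a),
        b=b,
        lam=lam0,
        grid_lam=lam_grid,
        grid_gamma=gamma_of_lambda(lam_grid),
    )
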