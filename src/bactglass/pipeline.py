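"""End-to-end orchestration of the glassy-dynamics analysis.

A movie is split into groups of consecutive frames (default 500, matching
the acquisition protocol the analysis targets); each group is analyzed
independently — area fraction φ, overlap function Q(Δt) with χ4Q,
orientation field with Cθ(Δt) and χ4θ, static structure factor, microdomain
areas, stretched-exponential fits of both relaxation channels — and the
per-group relaxation times are then assembled into τ(φ) and fitted with the
MCT power law and the VFT law for each channel. Comparing the two critical
area fractions φcθ and φcQ tests the two-step scenario: orientational
freezing before complete kinetic arrest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import dva, imgprep, orientfield, relaxfit, rodsim, sfactor
from .stack import ImageStack

logger = logging.getLogger("bactglass")

__all__ = [
    "AnalysisConfig",
    "GroupResult",
    "AnalysisSummary",
    "run_analysis",
    "compare_channels",
    "make_mct_series",
    "analyze_series",
]


@dataclass
class AnalysisConfig:
    """All knobs of the pipeline, serializable to/from YAML."""

    input_path: str | None = None
    pixel_size: float = 0.1724  # μm/px
    frame_interval: float = 0.0263  # s
    group_size: int = 500  # frames per analysis group
    roi: tuple[int, int, int, int] | None = None  # (x, y, w, h)
    correct_illumination: bool = True
    illumination_window_px: int | None = None
    sigma_px: float = 6.0  # structure-tensor scale
    grad_threshold: float = 1e-2  # (rad/μm)² on |∇θ|²
    min_domain_area_px: int = 4
    max_lag_frames: int | None = None
    vft_variant: str = "phi"
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.group_size < 10:
            raise ValueError("group size must be at least 10 frames")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("physical scales must be positive")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if raw.get("roi") is not None:
            raw["roi"] = tuple(raw["roi"])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        if d.get("roi") is not None:
            d["roi"] = list(d["roi"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class GroupResult:
    """Everything measured on one group of consecutive frames."""

    group_index: int
    phi: float
    phi_sd: float
    q_curve: dva.RelaxationCurve | None = None
    chi4_q: dva.SusceptibilityCurve | None = None
    c_theta: dva.RelaxationCurve | None = None
    chi4_theta: dva.SusceptibilityCurve | None = None
    sq: sfactor.StructureFactor | None = None
    fit_q: relaxfit.StretchedExpFit | None = None
    fit_theta: relaxfit.StretchedExpFit | None = None
    domain_areas: np.ndarray | None = None
    errors: dict = field(default_factory=dict)


@dataclass
class AnalysisSummary:
    """Cross-group synthesis: τ(φ) and the relaxation-law fits."""

    groups: list[GroupResult]
    mct_q: relaxfit.MCTFit | None = None
    mct_theta: relaxfit.MCTFit | None = None
    vft_q: relaxfit.VFTFit | None = None
    vft_theta: relaxfit.VFTFit | None = None
    domain_fit: orientfield.DomainAreaFit | None = None
    config_hash: str = ""

    def tau_table(self):
        """(phi, phi_sd, tau_Q, censored_Q, tau_theta, censored_theta) rows."""
        rows = []
        for g in self.groups:
            rows.append(
                (
                    g.phi,
                    g.phi_sd,
                    g.fit_q.tau if g.fit_q else np.nan,
                    g.fit_q.censored if g.fit_q else True,
                    g.fit_theta.tau if g.fit_theta else np.nan,
                    g.fit_theta.censored if g.fit_theta else True,
                )
            )
        return rows


def _analyze_group(
    stack: ImageStack,
    index: int,
    cfg: AnalysisConfig,
    phi_override: float | None = None,
) -> GroupResult:
    errors: dict = {}
    if cfg.correct_illumination:
        try:
            stack = imgprep.correct_illumination(stack, cfg.illumination_window_px)
        except ValueError as e:
            errors["illumination"] = str(e)
    est = imgprep.estimate_area_fraction(stack, seed=cfg.seed)
    phi = phi_override if phi_override is not None else est.phi
    res = GroupResult(group_index=index, phi=phi, phi_sd=est.phi_sd, errors=errors)
    lags = dva.default_lag_grid(stack.n_frames, cfg.max_lag_frames)
    try:
        res.q_curve = dva.overlap_function(stack, lags)
        res.chi4_q = dva.chi4_overlap(res.q_curve, phi)
    except (ValueError, RuntimeError) as e:
        errors["dva"] = str(e)
    try:
        ofield = orientfield.orientation_field(stack, cfg.sigma_px)
        res.c_theta = orientfield.orientational_correlation(ofield, lags)
        res.chi4_theta = orientfield.chi4_orientation(res.c_theta, phi)
        grad = orientfield.orientation_gradient_sq(ofield)
        areas = []
        for k in range(0, ofield.n_frames, max(1, ofield.n_frames // 10)):
            ds = orientfield.segment_microdomains(
                grad[k], cfg.pixel_size, cfg.grad_threshold, cfg.min_domain_area_px
            )
            areas.append(ds.areas)
        res.domain_areas = np.concatenate(areas) if areas else np.empty(0)
    except (ValueError, RuntimeError) as e:
        errors["orientation"] = str(e)
    try:
        res.sq = sfactor.static_structure_factor(stack)
    except (ValueError, RuntimeError) as e:
        errors["sfactor"] = str(e)
    for name, curve in (("fit_q", res.q_curve), ("fit_theta", res.c_theta)):
        if curve is None:
            continue
        try:
            setattr(
                res, name,
                relaxfit.fit_stretched_exponential(curve, allow_censored=True),
            )
        except (ValueError, RuntimeError) as e:
            errors[name] = str(e)
    for stage, msg in errors.items():
        logger.warning("group %d stage %s failed: %s", index, stage, msg)
    return res


def run_analysis(
    config: AnalysisConfig,
    stack: ImageStack | None = None,
    phi_overrides: list[float] | None = None,
) -> AnalysisSummary:
    """Group-wise analysis of one movie plus cross-group law fits.

    ``stack`` may be passed directly (e.g. a rendered synthetic movie);
    otherwise it is read from ``config.input_path``. ``phi_overrides``
    substitutes known ground-truth area fractions per group for the
    measured ones (used with synthetic data).
    """
    from .stack import read_stack

    if stack is None:
        if config.input_path is None:
            raise ValueError("no input movie: set input_path or pass a stack")
        stack = read_stack(config.input_path, config.pixel_size, config.frame_interval)
    if config.roi is not None:
        stack = imgprep.crop_roi(stack, config.roi)
    groups = []
    n_groups = max(1, stack.n_frames // config.group_size)
    for gi in range(n_groups):
        sub = ImageStack(
            stack.frames[gi * config.group_size : (gi + 1) * config.group_size],
            stack.pixel_size,
            stack.frame_interval,
        )
        phi_ov = phi_overrides[gi] if phi_overrides is not None else None
        groups.append(_analyze_group(sub, gi, config, phi_ov))
    return _summarize(groups, config)


def analyze_series(
    stacks: list[ImageStack],
    config: AnalysisConfig,
    phi_overrides: list[float] | None = None,
) -> AnalysisSummary:
    """Analyze a series of movies, one group per movie (synthetic series)."""
    groups = []
    for gi, stack in enumerate(stacks):
        phi_ov = phi_overrides[gi] if phi_overrides is not None else None
        groups.append(_analyze_group(stack, gi, config, phi_ov))
    return _summarize(groups, config)


def _summarize(groups: list[GroupResult], config: AnalysisConfig) -> AnalysisSummary:
    summary = AnalysisSummary(groups=groups, config_hash=config.config_hash())
    for channel, mct_attr, vft_attr in (
        ("fit_q", "mct_q", "vft_q"),
        ("fit_theta", "mct_theta", "vft_theta"),
    ):
        phis, taus = [], []
        for g in groups:
            f = getattr(g, channel)
            if f is not None and not f.censored:
                phis.append(g.phi)
                taus.append(f.tau)
        if len(phis) >= 4:
            try:
                setattr(summary, mct_attr, relaxfit.fit_mct(phis, taus))
                setattr(
                    summary, vft_attr,
                    relaxfit.fit_vft(phis, taus, config.vft_variant),
                )
            except (ValueError, RuntimeError) as e:
                logger.warning("law fit failed for %s: %s", channel, e)
    all_areas = np.concatenate(
        [g.domain_areas for g in groups if g.domain_areas is not None]
        or [np.empty(0)]
    )
    a_min = config.min_domain_area_px * config.pixel_size**2
    if len(all_areas[all_areas >= a_min]) >= 30:
        summary.domain_fit = orientfield.fit_domain_areas(all_areas, a_min)
    return summary


@dataclass
class ChannelComparison:
    """The two-step-transition report: does orientation freeze first?"""

    phi_c_theta: float | None
    phi_c_q: float | None
    difference: float | None  # φcQ − φcθ
    difference_ci: tuple[float, float] | None
    theta_freezes_first: bool | None  # significant at 95%?
    partial: bool = False


def compare_channels(summary: AnalysisSummary) -> ChannelComparison:
    """Compare the orientational and translational critical fractions.

    The difference φcQ − φcθ carries a CI propagated from the two fits'
    95% intervals (independent-error quadrature); ``theta_freezes_first``
    is True only when the whole CI lies above zero.
    """
    mq, mt = summary.mct_q, summary.mct_theta
    if mq is None or mt is None:
        return ChannelComparison(
            phi_c_theta=mt.phi_c if mt else None,
            phi_c_q=mq.phi_c if mq else None,
            difference=None, difference_ci=None,
            theta_freezes_first=None, partial=True,
        )
    diff = mq.phi_c - mt.phi_c
    hw_q = (mq.phi_c_ci[1] - mq.phi_c_ci[0]) / 2
    hw_t = (mt.phi_c_ci[1] - mt.phi_c_ci[0]) / 2
    hw = float(np.hypot(hw_q, hw_t))
    return ChannelComparison(
        phi_c_theta=mt.phi_c,
        phi_c_q=mq.phi_c,
        difference=diff,
        difference_ci=(diff - hw, diff + hw),
        theta_freezes_first=bool(diff - hw > 0),
    )


# ---------------------------------------------------------------------------
# synthetic benchmark series


def make_mct_series(
    phi_levels: np.ndarray | None = None,
    phi_c: float = 0.882,
    gamma: float = 1.6,
    tau_at_first: float = 0.2,
    n_frames: int = 200,
    shape: tuple[int, int] = (64, 64),
    seed: int = 0,
    noise_amplitude: float = 0.01,
    well_radius_factor: float = 2.0,
    interacting: bool = False,
) -> list[dict]:
    """Rod-movie series whose relaxation times follow an imposed MCT law.

    Each density level is a rendered rod movie whose propulsion speed is set
    inversely to the target relaxation time τ(φ) = τ1 · [(φc − φ1)/(φc − φ)]^γ
    (τ1 = ``tau_at_first`` at the lowest level): image decorrelation of
    ballistically moving rods happens when a rod travels about its own
    width, so the overlap relaxation time tracks width/speed. Measured
    through the pipeline (Q curve → stretched-exponential τ → MCT fit), the
    fitted φc of the resulting τ(φ) recovers the generating value.

    By default the rods in this series do not interact sterically
    (``interacting=False``): the point of the fixture is that the imposed
    law is the *only* density dependence of τ, whereas emergent crowding
    would superimpose its own slowdown on the dial. Set
    ``interacting=True`` for movies with steric alignment and collisions
    (the law then holds only approximately).

    Returns one dict per level with keys ``phi_nominal``, ``phi_true``
    (rendered in-frame coverage), ``stack``, ``tau_target``.
    """
    if phi_levels is None:
        phi_levels = np.linspace(0.60, 0.79, 8)
    phi_levels = np.asarray(phi_levels, float)
    if np.any(phi_levels >= phi_c):
        raise ValueError("all density levels must lie below phi_c")
    out: list[dict] = []
    tau1 = tau_at_first
    phi1 = phi_levels[0]
    width = 1.0
    mean_len = 2.75
    for i, phi in enumerate(phi_levels):
        tau = tau1 * ((phi_c - phi1) / (phi_c - phi)) ** gamma
        speed = width / tau
        optics = rodsim.OpticsParams(
            shape=shape, noise_amplitude=noise_amplitude, noise_seed=seed + 1000 + i
        )
        # the imaged region sits deep inside the well, as in the real
        # protocol (ROI near the well center), so wall accumulation and the
        # wall depletion zone stay outside the frame
        well_radius = (
            0.5 * np.hypot(*shape) * optics.pixel_size * well_radius_factor
        )
        # rod centers are confined to radius R - L/2, so the bulk (imaged)
        # density is set by the accessible area, not the full well area
        accessible_radius = well_radius - mean_len / 2
        n_rods = rodsim.seed_count_for_area_fraction(
            phi, accessible_radius, mean_len, width
        )
        params = rodsim.SimParams(
            n_rods=n_rods,
            well_radius=well_radius,
            rod_width=width,
            initial_length=(2.0, 3.5),
            speed=speed,
            repulsion_k=200.0 if interacting else 0.0,
            noise_rot=0.5,
            noise_trans=0.002,
            growth_rate=0.0,
            dt=1e-3,
            duration=(n_frames - 1) * 0.0263,
            seed=seed + i,
        )
        ensembles = rodsim.simulate_rods(params)
        stack = rodsim.render_frames(ensembles, optics)
        gt = rodsim.ground_truth(ensembles, optics)
        out.append(
            {
                "phi_nominal": float(phi),
                "phi_true": float(np.mean(gt["area_fraction"])),
                "stack": stack,
                "tau_target": float(tau),
            }
        )
    return out


def recover_mct_from_series(series: list[dict]) -> dict:
    """Measure τQ(φ) on an MCT-law movie series and refit the law.

    The end-to-end chain the series exists to validate: overlap function of
    each movie, stretched-exponential fit for τQ, then the MCT power-law
    fit of τQ against the series' generating density levels (the variable
    the law was imposed on; the realized per-movie coverage is reported
    alongside). Censored levels (no relaxation inside the window) are
    excluded from the law fit.
    """
    phis, taus, rows = [], [], []
    for lv in series:
        curve = dva.overlap_function(lv["stack"])
        f = relaxfit.fit_stretched_exponential(curve, allow_censored=True)
        rows.append(
            {
                "phi_nominal": lv["phi_nominal"],
                "phi_true": lv["phi_true"],
                "tau_target": lv["tau_target"],
                "tau_measured": f.tau,
                "beta": f.beta,
                "censored": f.censored,
            }
        )
        if not f.censored:
            phis.append(lv["phi_nominal"])
            taus.append(f.tau)
    mct = relaxfit.fit_mct(phis, taus)
    return {"mct": mct, "levels": rows}
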