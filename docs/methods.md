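# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind `bactglass`. It is written for someone who wants to
understand *why* the code does what it does, or to judge what a passing
test suite does and does not establish about real data.

## Analysis substrate and conventions

All analysis operates on an `ImageStack`: a `(T, H, W)` intensity array
with a pixel size (μm/px) and frame interval (s). Pixel `(0, 0)` is the
top-left corner, x runs rightward along columns, y runs *upward* in the
physical frame (downward in array rows), and pixel centers sit at
half-integer pixel coordinates. Angles are measured from +x,
counterclockwise in the physical frame. Every module — rendering, ground
truth, structure tensor, segmentation — uses this one convention; the
rotation-equivariance and single-rod tests pin it down.

Nematic angles (head–tail symmetric) live in [−π/2, π/2). All angle
arithmetic goes through `nematic_diff`, which wraps differences into that
range modulo π; 80° − (−80°) is a −20° reorientation, not +160°.

## Differential variance analysis

The overlap function is

    Q(Δt) = 1 − V(Δt) / V(∞),
    V(Δt) = ⟨[I(r, t+Δt) − I(r, t)]²⟩_{r,t},   V(∞) = 2·Var_{r,t}[I].

For a frozen scene V(Δt) = 0 and Q = 1; for a fully decorrelated scene the
difference variance is twice the static variance and Q = 0. Q behaves like
a self-intermediate scattering function but needs no segmentation or
tracking. Reference-time averaging uses *all* admissible (overlapping)
frame pairs; the statistical dependence between overlapping pairs is
accepted — it biases no mean, only the naive error bars, which we do not
report for Q itself.

V(∞) is pooled over the whole analysis group (default 500 frames, the
standard acquisition block for this kind of experiment; a config knob).
Camera noise enters Q as a constant floor: for a static scene with iid
noise of variance σ², Q saturates at 1 − 2σ²/V(∞) rather than 1. The
noise-floor test verifies this analytic value; the stretched-exponential
fit's free amplitude absorbs it in practice.

The dynamic susceptibility is

    χ4Q(Δt) = φ · [⟨Q(t,Δt)²⟩_t − ⟨Q(t,Δt)⟩_t²],

the population variance over reference times of the instantaneous
overlap, scaled by the area fraction. The per-reference-time samples are
carried on every `RelaxationCurve`, so χ4 is exactly consistent with the
curve it came from. For synthetic data the prefactor φ is the ground-truth
covered fraction; for real data, the measured φ of the same group.

Lag grids are pseudo-logarithmic in frames (1, 2, 3, 4, 6, 8, 11, 16, …;
successive ratio √2) capped at half the group length — relaxation beyond
half the observation window is not reliably sampled and is instead
reported as censored (below).

## Orientation field

The per-pixel nematic orientation comes from the structure tensor: Gaussian
derivative gradients (gx, gy), tensor products ⟨gx²⟩, ⟨gxgy⟩, ⟨gy²⟩
smoothed with a Gaussian at the integration scale σ (default 6 px, i.e.
~1 μm at the default optics — about one cell width), and the half-angle
arctangent θ_grad = ½·atan2(2⟨gxgy⟩, ⟨gx²⟩−⟨gy²⟩). Intensity varies
fastest *across* a rod, so the returned structure axis is θ_grad + π/2,
which matches the rod axis; a rendered single rod at 30° pins the
convention to within fractions of a degree.

**Two scales, not one.** The derivative kernel uses a fine scale
(default 1 px), the tensor smoothing the coarse integration scale σ. A
single-scale tensor (derivative kernel at σ = 6 px) attenuates intensity
structure at wavelengths below ~2πσ — which includes everything at the
width of a cell — by orders of magnitude, leaving the tensor at the noise
floor on exactly the images this analysis targets; the two-scale form is
the standard texture-orientation estimator and is what the accuracy
guarantees are stated for.

Pixels whose tensor trace falls below 10⁻⁶ × the frame variance are
masked (NaN) rather than assigned θ = 0: a featureless region has no
orientation. Masks propagate pairwise through Cθ and through the gradient
stencils.

The orientational correlator Cθ(Δt) = ⟨cos 2Δθ⟩ is evaluated on the
coarse-grained field at every unmasked pixel (field-based, not per-cell);
χ4θ uses the same estimator as χ4Q. |∇θ|² uses central differences
(one-sided at edges), each difference nematically wrapped so a 0°/180°
domain wall does not produce a spurious π jump, divided by the physical
spacing: units (rad/μm)².

**Microdomains.** Boundary pixels are those with |∇θ|² at or above a
threshold (default 10⁻² (rad/μm)², applied to the *squared* gradient — the
threshold's dimensions match the squared quantity; the exponent is
configurable). Domains are 4-connected components of the rest
(4-connectivity avoids diagonal leakage through 1 px boundaries);
components under 4 px are quantization debris and dropped; border-touching
domains are flagged, and both included and excluded tallies are emitted,
since either convention is defensible. Domain areas are fitted with a
left-truncated exponential by maximum likelihood: for samples above the
truncation point A_min, the memoryless property gives
Â0 = mean(A − A_min), with standard error Â0/√n — binning-free, with a
well-defined CI. The truncation default is the 4 px minimum countable
area.

## Static structure factor

Per frame: subtract the frame mean (the bare transform would be dominated
by the q = 0 peak), 2D FFT, squared modulus, average over frames;
normalized by the pixel count so Parseval reads ΣS = N_px·Var[I]. The
overall scale is arbitrary, as for any image structure factor; shapes and
ratios are meaningful. Wavenumbers are physical: q = 2πk/(N·pixel size).
Radial averaging uses annuli one frequency step of the shorter axis wide
and excludes the DC bin. No window function by default (config flag for
Hann).

## Relaxation-law fits

Stretched exponential a·exp[−(Δt/τ)^β] is fitted to each relaxation curve
by trust-region least squares with a deterministic multi-start over
β ∈ {0.5, 1.0, 1.5}; τ is parameterized as log τ for conditioning;
amplitude bounded in (0, 1.5]. 95% CIs come from the linearized covariance
with Student-t critical values. When a curve never decays below 1/e of its
initial plateau inside the window, τ is not identified: the fit is flagged
`censored` (τ is then a lower bound) and excluded from law fits — glassy
groups whose relaxation exceeds the observation time are informative about
ordering, not about τ.

The law fits operate on log τ (τ spans decades; log space weights decades
evenly): MCT as log τ = log a − γ log(φc − φ) with φc free (bounded below
by the largest observed φ; multi-start over its initial offset), VFT as
log τ = log A + cφ/(φ_VFT − φ). The VFT form with φ in the numerator is
the default; the plain `exp[c/(φ_VFT − φ)]` variant is a config switch,
since both parameterizations circulate. Rescaling τ → aτ moves only the
amplitude — checked by test.

**Thermal MCT exponent bound.** The exponent relations
λ = Γ(1−a)²/Γ(1−2a) = Γ(1+b)²/Γ(1+2b) with γ = 1/(2a) + 1/(2b) are solved
by bracketed root-finding (both sides are monotone in their argument). At
the admissible boundary λ = 1/2, b = 1 exactly (Γ(2)²/Γ(3) = 1/2), giving
γ_min = 1/(2a) + 1/2 ≈ 1.765; γ(λ) is increasing on [1/2, 1), so this is
the minimum. A measured γ below γ_min is impossible for thermal MCT and
flags athermal (active) dynamics.

## Area fraction

Pre-processing divides each frame by its Gaussian-weighted local mean
(window default 2⌊min(H,W)/16⌋+1 px, Gaussian σ = window/4, mirror
padding) — flat regions map to ~1, and the operation is idempotent to 1%.

The binarization threshold comes from 3-class fuzzy c-means (fuzziness
m = 2, tol 10⁻⁵, centers initialized at the 0.1/0.5/0.9 intensity
quantiles — deterministic). The darker/rest cutoff is the midpoint of the
*lowest and highest* class centers. Rationale: for dark objects on a
bright field under optical blur, the blurred edge crosses the halfway
intensity exactly at the geometric boundary, so this midpoint recovers
the true covered fraction without a blur-dependent bias; the midpoint of
the two lowest centers (available as `rule="low_mid"`) counts only the
dark core and systematically underestimates φ — on rendered ground-truth
movies by up to 0.12. A unimodal-histogram guard (center span below
6.5× the within-class spread — a unimodal Gaussian split three ways gives
~5.6 regardless of scale) warns and thresholds below the intensity bulk:
an image with no contrast carries no evidence of a dark phase.

## The rod simulator

`rodsim` exists to give every stage exact ground truth. The model is
deliberately minimal: overdamped Langevin spherocylinders, self-propelled
along their axes at signed speeds, with harmonic overlap repulsion (force
at the closest-approach point between shaft segments, torque from its
lever arm, slender-rod rotational mobility 12/L²), a repulsive wall, and
exponential elongation with symmetric midpoint division (daughters get
new track ids, the mother recorded as parent, a small orientation kick,
and resampled speeds). Euler–Maruyama integration; the sub-step is
rounded so an integer number of steps exactly tiles the frame interval;
a non-finite state aborts with the time step named. Determinism: one
`numpy` Generator seeded from `SimParams.seed` drives everything.

Rendering draws each rod as a dark spherocylinder on a bright field with
a smoothstep intensity edge of half-width 0.15 μm centered on the
geometric boundary — the half-level contour coincides with the true rod
outline (so threshold-based area estimates are unbiased), overlapping
rods combine by maximum darkening (touching parallel cells leave a
brighter seam, as phase contrast does), then Gaussian blur at the optical
resolution and seeded additive noise. Defaults mirror the target optics:
0.1724 μm/px, 0.258 μm resolution, 26.3 ms frame interval, ~1 μm wide
cells 2–6 μm long.

What the simulator does **not** emulate: phase-contrast halos, run-and-
tumble statistics, hydrodynamic interactions, 3D buckling, illumination
drift, and cell-interior texture beyond the edge profile. Consequently a
passing suite shows the *estimators* are correct on images with the right
geometry and noise scales — not that segmentation or the structure tensor
will meet the same error bars on real phase-contrast data.

Two geometric facts matter when designing fixtures. Rod centers are
confined to radius R − L/2, so the *bulk* density exceeds the well-average
density by (R/(R − L/2))²; fixtures that care about the imaged density
compute rod counts from the accessible area. And persistent rods
accumulate at the wall whenever their persistence length v/(2D_r) is
comparable to R, draining the imaged center; stationary fixtures use
short persistence and a burn-in, and the imaged region sits well inside
the well, as in the experiment this emulates.

## The imposed-slowdown benchmark series

`pipeline.make_mct_series` builds the end-to-end recovery benchmark: 8
density levels (0.60–0.79), 200 frames each at 64×64 px, where each
level's propulsion speed is set to v = width/τ_target with
τ_target(φ) = τ1·[(φc − φ1)/(φc − φ)]^γ, φc = 0.882, γ = 1.6, τ1 = 0.2 s.
Image decorrelation of a ballistic rod happens when it travels about its
own width, so τQ measured through the pipeline tracks the imposed law up
to a constant the MCT amplitude absorbs. Steric interactions are *off* in
this series (a flag): the fixture's purpose is that the imposed law is
the only density dependence of τ; with collisions on, emergent crowding
superimposes its own slowdown on the dial and the recovered exponents
mix the two effects. The law fit uses the generating density levels as
abscissa and reports the realized per-movie coverage alongside.
Qualitative crowding physics — a dense interacting movie relaxing more
slowly than a dilute one at equal activity — is asserted separately on
interacting simulations.

## Tracking

Segmentation is classical: fuzzy-c-means threshold, morphological
opening, then a watershed on the smoothed distance transform whose
markers are per-component cores (pixels above 60% of that component's
distance maximum). A rod's ridge is one marker — no fragmentation — while
blobs with separate cores joined by thin necks split. Equal-width rods
touching side-by-side or end-to-end produce no distance-transform valley
at the contact and cannot be split this way; in rendered images the
brighter seam between touching cells usually separates them at the
threshold stage instead. Centroid, nematic axis, and length come from
each component's second-moment ellipse; components under 4 px are
discarded.

Linking is global nearest-neighbor assignment per frame pair (Hungarian
algorithm on squared displacement) with a hard per-link cutoff; unmatched
detections start new tracks, track heads survive a configurable number of
missed frames, and a disappearing mother with two appearing daughters is
*not* joined across a division — per-cell displacement statistics must
not mix lineages. Ambiguous optima resolve deterministically to the
lowest index.

The displacement–orientation histogram folds the angle between a cell's
displacement over a lag and its nematic axis (nematic mean of the two
endpoint axes — the midpoint convention) into [0°, 90°]; displacements
below a resolution floor are excluded and counted. The velocity
correlation ⟨v_i·v_j⟩ uses centroid-difference velocities (default lag
2 frames ≈ 0.053 s) binned by instantaneous pair distance (default
0.5 μm bins), with standard errors treating pairs as independent. Cage
escapes are flagged descriptively: displacement across a trailing 2 s
window exceeding two cell widths.

## Problem sizes in the tests

The suite runs movies of 31–200 frames at 48–128 px — large enough that
every estimator operates in its intended regime (tensor scales, lag
grids, FCM classes), small enough to iterate on. The same code paths
handle 500-frame, 259×214 px experimental groups unchanged; nothing in
the implementation is specialized to the test sizes. Stochastic
guarantees (CI coverage, null correlations) use fixed seeds and are exact
statements about those seeds; the margins chosen (e.g. ≥90/100 coverage
for a 95% CI) leave room for ordinary sampling variation.

## Known limitations

- Q and Cθ error bars are not propagated into the stretched-exponential
  CIs beyond the least-squares residuals; overlapping reference times make
  the effective sample size smaller than the nominal one.
- The exponential domain-area fit assumes the exponential form; it is a
  scale estimator, not a goodness-of-fit test.
- The structure tensor's accuracy degrades where neighboring cells at
  discordant orientations fall inside one integration scale — i.e. at
  domain walls and defects; the coarse-grained field there is a smooth
  interpolation, not the per-cell angle.
- The segmentation is a classical stand-in adequate for rendered rods and
  modest densities; densely packed real images are the province of
  learned segmenters, and the tracking statistics accept detections from
  any source.
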