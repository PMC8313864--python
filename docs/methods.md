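# Methods

This note records the models, numerical choices and known limitations of
the package, in the spirit of a methods appendix.

## The light-switched three-compartment model (`kinetics`, `normfit`)

The cell is reduced to three well-mixed pools — mitochondria-bound (M),
free cytoplasmic (C) and nuclear (N) fractions of total fluorescence — with
first-order exchange: binding/unbinding at the mitochondrial surface
(k_on, k_off) and nuclear import/export (k_imp, k_exp). The light state
switches (k_on, k_off) between dark and lit values; illumination is treated
as continuously on during lit frames, because the within-frame illumination
duty cycle is far shorter than any transport timescale and oscillatory-rate
variants create a badly multimodal fitting landscape for no extra
information. Photobleaching is deliberately absent from the ODE: it is
removed upstream by normalization, after which M + C + N is conserved and
equals one.

This reduction assumes diffusion is fast relative to translocation, so the
free pools are spatially homogeneous at all times. The FRAP module contains
the numerical counterpart of that assumption (below).

**Integration.** The system is linear with piecewise-constant coefficients.
`simulate_trace` restarts an adaptive explicit Runge–Kutta integrator
(SciPy's RK45, rtol 1e-9, atol 1e-13) at every light switch so the
coefficient discontinuity is never smoothed across. The fitting routines
use a second path — exact propagation through the eigendecomposition of
each phase's generator matrix — which is ~100× faster and agrees with the
RK path to ~1e-10; the two are cross-checked in the test suite. (RK45
rather than a higher-order scheme: on long smooth phases the high-order
dense interpolant of DOP853 loses ~3 digits at the frame times, RK45's does
not.)

**Normalization.** Background (mean of an extracellular ROI over time) is
subtracted per frame, negatives floored at zero and counted. Bleaching is
corrected by fitting one line per contiguous illumination phase to the
total M + C + N (laser load, and hence bleach rate, differs between release
and recovery), excluding the first 20% of each phase where transients and
noise are worst, then dividing all compartments by the fitted total. The
20% exclusion is a package default; the original procedure excludes "early"
frames without quantifying. With noisy data the normalized sum is 1 only on
average; `renormalise_per_frame` closes the constraint exactly before
fitting.

**Fitting.** Trust-region nonlinear least squares (SciPy `least_squares`,
TRF) with non-negativity bounds and a small multi-start (3 jittered starts,
seeded) against local minima. Initial conditions are reduced through the
dark steady state: M0 is a fitted parameter (guess: median mitochondrial
signal over the five pre-release dark frames), C0 and N0 follow from
N0/C0 = k_imp/k_exp and the sum constraint. Each compartment's residuals
are divided by that compartment's observed standard deviation so all three
contribute equally regardless of dynamic range — the stated goal of the
original weighting, realized here as 1/sd scaling. Confidence intervals are
curvature-based (Gauss–Newton covariance at the optimum, 95%); parameters
whose Jacobian column vanishes (e.g. lit rates fitted to an all-dark trace)
are flagged unidentifiable and given infinite intervals rather than
silently reported.

**Phase-restricted fits.** `phase_restricted_ci` refits using only the
release frames (pre-dark + lit), only the recovery frames (with a free
initial state, since recovery starts far from the dark equilibrium, and
with lit rates flagged unidentifiable), or both. The per-compartment
weights are always taken from the full trace so interval widths are
comparable across restrictions; with per-restriction weights the
comparison would confound information content with weighting convention.

**Model comparison.** AIC in the Gaussian-residual form n ln(RSS/n) + 2k,
with k counting fitted parameters plus one for the residual variance (the
original work does not state its AIC form; this is the standard choice for
least-squares fits). "AIC probability" is interpreted as the Akaike weight
exp(−Δᵢ/2)/Σ exp(−Δⱼ/2) within the compared set. The variant family spans
single vs dual on rates and free / fixed / ratio-fixed dark rates; fixed
values (e.g. FRAP medians) are supplied by configuration rather than baked
in, since they are experiment-specific.

**Known sensitivity.** Scaling all compartments together (expression level)
leaves fitted rates exactly unchanged — the normalization divides it out.
Scaling one compartment alone (a per-compartment gain error) is *not*
exactly absorbed: it turns the measured total into 1 + (γ−1)M(t), which a
per-phase line cannot fit away, so rate estimates shift by roughly the same
relative order as the miscalibration (measured: ≈3–7% shift for a 5% gain
error). Since all three compartments are read from the same protein
channel on the same detector, only small relative errors are physical; the
test suite pins the measured sensitivity rather than claiming exact
invariance.

## FRAP reaction–diffusion model (`frap`)

On the seconds timescale of FRAP, nuclear translocation is negligible and
the model is free diffusion of the unbleached cytoplasmic pool c plus
first-order exchange with an immobile mitochondria-bound pool m, with
photobleaching proportional to local laser intensity. k_on = r_on·S_M is
treated as a constant scalar (binding sites in excess); a per-pixel binding
density map is supported for heterogeneity studies.

**Discretization.** 5-point finite-difference Laplacian on the pixel grid,
masked to the cytoplasm, zero-flux boundaries by mirror ghost values (the
assembled operator is symmetric with zero row sums, so diffusion conserves
mass exactly). Time stepping is Strang splitting: an exact pixelwise
solution of the 2×2 binding exchange (eigenvalues 0 and −(k_on+k_off))
around a Crank–Nicolson diffusion half/full step, factorized once per
simulation (`splu`) and reused. Default substep 0.05 s against 0.5 s
frames. The bleach pulse is applied as an instantaneous attenuation
exp(−α·I(x)·Δt_bleach) between frames; the continuous loss law is the
model's, the pulse integration is ours. The low uniform imaging
illumination between frames commutes exactly with both diffusion and
exchange and is applied as a closed-form per-frame factor.

**Bleach profiles.** The empirically calibrated spot profiles used
originally (fixed-cell measurements at radii 10/15/20 px ≙ 2.6/4.0/5.3 μm,
i.e. 0.13 μm/px) are not published as data; the package's
"empirical-like" profile is a synthetic stand-in — a hard disk convolved
with a Gaussian edge (σ = 2 px default). A hard-disk profile is also
available.

**Fitting.** (D_c, k_on, k_off, α) by bounded least squares on radial-bin
residuals around the bleach center (default, for speed and noise
averaging) or full per-pixel residuals. Because data and model share the
solver, solver bias cancels in self-consistency studies; the practically
relevant accuracy question is the solver's agreement with the analytic
limits, which the test suite checks (stationarity at α = 0, diffusion
uniformity, mass monotonicity, the ODE limit below).

**Numerical counterparts of the asymptotic arguments.** Two consistency
checks tie the PDE to the compartment ODE: (i) the stationary no-bleach
state, computed directly as the null space of the assembled spatial
operator, has a spatially uniform free pool (CV ≲ 1e-14) even when binding
sites are heterogeneous — the free concentration satisfies Laplace's
equation with zero-flux boundaries, whose only solutions are constants;
(ii) when D is large relative to the exchange rates, compartment-integrated
PDE dynamics after a bleach match the two-compartment ODE to well under 1%
even when binding sites colocalize with the bleach spot, and deviate
(several %) when D is made artificially small — the regime boundary of the
well-mixed reduction.

## FLIP model (`flip`)

Repeated bleaching of one compartment while both are monitored. Normalized
totals n(t), c(t) exchange via k_imp/k_exp; the bleached compartment
additionally loses signal at hazard h(t). The original equations are not
recoverable from the source text body, so the hazard form is this package's
interpretation, chosen to reproduce the stated behaviour: h(t) = η₁ +
η₂ e^{−λt}, a fast early component relaxing to a slow constant rate,
making the bleached compartment's decay effectively double-exponential (a
single constant hazard demonstrably underestimates the rapid initial
loss). Bleaching enters the ODE continuously rather than as discrete 2 s
pulses — pulse period ≪ transport timescales.

**Two solution routes.** The production path is adaptive RK (rtol 1e-11).
The verification path expands the solution in powers of e^{−λt}: the
time-varying system x′ = (A + B e^{−λt})x embeds exactly into a
constant-coefficient block-bidiagonal system with blocks A + kλI and
subdiagonal B, solved by matrix exponential and resummed. Truncation at
order 40 is far below 1e-8 for hazard amplitudes with η₂/λ up to ~3
(protocol-realistic); the two routes agree to ~1e-12 and serve as mutual
oracles.

**Fitting.** (k_imp, k_exp, η₁, η₂, λ, c0) by bounded least squares with
n0 eliminated via the steady state n0 = (k_imp/k_exp)c0. Initial guesses:
c0 from the first cytoplasmic point, transport rates of order 1e-3 s⁻¹,
bleach parameters from a double-exponential fit A₁e^{−r₁t} + A₂e^{−r₂t}
(r₁ ≤ r₂) to whole-cell intensity, mapped as η₁ = r₁, λ = r₂ − r₁,
η₂ = (A₂/(A₁+A₂))λ (the excess hazard amplitude at t = 0). Flat traces
are flagged unidentifiable.

## Segmentation engine (`segment`)

Per-channel moving percentile projections denoise the movie: the movie is
partitioned into windows (default length half the movie; the last window
absorbs any remainder), each window's per-pixel percentile image serves all
frames it covers. Thresholds defined at window centers ("seeding points")
are interpolated linearly between seeds and held constant outside the first
and last. Cell boundary segmentation uses a hybrid channel — per-frame
pixelwise max over the three channels after per-channel min–max rescaling
over the movie (so detector gain differences cannot let one channel
dominate; the original is silent on rescaling). The cell is the largest
connected component of the thresholded hybrid (holes filled, ties broken by
centroid proximity to the image center), the nucleus the largest component
inside it, mitochondria the thresholded marker inside the cell minus the
nucleus, cytoplasm the remainder. Mask set relations (nucleus ⊆ cell,
disjointness, cytoplasm = cell ∖ (nucleus ∪ mitochondria)) are enforced
structurally.

Seeding is manual in the original interactive tool; here seeds are supplied
programmatically or default to automatic levels per seed projection: Otsu
for the bimodal marker channels — refined to the midpoint of the two class
means, because histogram-bin Otsu lands at the edge of the background noise
when the foreground mode is far away — and the triangle method for the
hybrid channel, whose histogram is background-dominated with several
foreground modes (cytoplasm much dimmer than nucleus). Default percentiles
(nucleus 50th, mitochondria 90th, hybrid 90th) are package choices; the
original leaves them to the user.

Signal extraction sums the protein channel over each compartment mask per
frame; empty compartments are recorded as missing (NaN), never as zero.
Regional gain maps follow the published recipe exactly: mean of five
pre-light frames, mean of five frames after 200 s of light, ratio × 256,
2×2 mean-binned, stored 16-bit (ratio 1 ⇒ 256 exceeds 8-bit range) with a
clipped 8-bit export. Pulse averaging treats each isolated lit frame in a
staggered schedule as a technical replicate, requires equal pulse spacing,
and reports per-offset mean ± sd plus peak and post-peak decline rate.

## Synthetic data (`synthkit`)

The generator emulates the study conditions: an elliptical cell
(default 256×256 px at 0.2 μm/px) with an offset elliptical nucleus;
mitochondrial filaments grown as persistent random walks (heading noise
0.35 rad/step) confined to the cytoplasm and dilated to 2 px width, spawned
until they cover ~30% of the non-nuclear cell area; protein distributed
uniformly within each compartment in proportion to the ODE trace; static
marker textures at ~3× the mean protein brightness; per-phase linear
photobleaching (defaults 4e-4/frame lit, 1e-4/frame dark) continuous
across phase boundaries; Gaussian detection noise with sd = 1% of signal
plus a small floor (a Poisson–Gaussian stand-in). All generators are
deterministic under a fixed seed, and every movie carries its ground truth
(masks, proportions, bleach factor, spec).

Default protocols are the study's: opto-standard (5 dark + 150 lit + 150
dark at 4 s — frames 6–155 lit in 1-based counting), opto-staggered
(80 lit + 4 × (19 dark + 1 lit)), FLIP (3 pre-bleach + 150 frames at 2 s
with interleaved 2 s bleaches), FRAP (2.6 μm spot, 0.5 s frames). Default
kinetic constants are the reported dark-state binding medians
(0.027/0.019 s⁻¹), an unchanged lit on rate, a severalfold-raised lit off
rate (0.085 s⁻¹) and nuclear transport of order 2e-3 s⁻¹.

**What passing tests do and do not show.** The renderer has no
point-spread function, no compartment-internal texture in the protein
channel, no cell movement and no focus drift; segmentation Jaccards near
1.0 on synthetic movies therefore demonstrate correctness of the
engine's logic, not its performance on real microscopy. Conversely the
parameter-recovery results are meaningful precisely because the generative
model matches the fitted model — they isolate estimator correctness and
identifiability (which phases pin which parameters, how noise propagates to
CIs) from model misspecification, which must be assessed on real data.

## Interfaces

Traces travel as CSV (time_s, lit, M, C, N, normalized), schedules as JSON
block lists, stacks as TIFF with a metadata dict (axes TCYX, channel
roles, pixel size, frame interval; proprietary microscope formats are
supported only via prior conversion to TIFF), fits as JSON, cohorts as one
CSV row per cell. The CLI is a thin wrapper over these functions; every
run writes a resolved-config copy next to its artifacts so any output is
reproducible from config + seed.

## Problem sizes used in the shipped studies

Unit and acceptance studies run on desk-scale versions of the study
conditions chosen once: 160×160 px synthetic cells for end-to-end studies
(20 seeds at 1% noise), the full 128×128 grid for the FRAP
diffusivity-recovery benchmark (5 pre-bleach + 40 recovery frames at
0.5 s), 64×64 grids for PDE consistency checks, and the full 305-frame
standard protocol everywhere the opto ODE is fitted. These sizes keep every
study comfortably reproducible on a single CPU while leaving the estimator
problems (identifiability, noise propagation) unchanged.

## Known limitations

- 2-D only; 3-D light-sheet segmentation and rendering are out of scope.
- The FRAP "empirical-like" bleach profile is a synthetic stand-in for the
  unpublished fixed-cell calibration.
- The FLIP hazard parameterization is an interpretation consistent with
  the described double-exponential behaviour, not a verbatim reproduction.
- Curvature CIs are local Gaussian approximations; strongly correlated or
  boundary-pinned parameters deserve profile likelihood (not implemented).
- The bilinear bleach correction assumes linear per-phase loss; strongly
  nonlinear bleaching would bias proportions and therefore rates.
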