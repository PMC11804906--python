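# Methods

This note documents the models, conventions, and numerical choices behind
escrtkit, and what the synthetic benchmarks do and do not establish.

## Coordinate and format conventions

All public geometry is in Ångström, with the origin at the centre of the
top-left pixel, x along columns and y along rows. STAR files carry pixel
coordinates and are converted at the I/O boundary; the extra per-pick
columns (edge id, arc length, tangent angle) use the RELION helical labels
(`rlnHelicalTubeID`, `rlnHelicalTrackLengthAngst`, `rlnAnglePsi`). MRC maps
are single-section float32 MRC2014, read and written through gemmi; a
header without a positive pixel size falls back to 1.0 Å with a warning.
Trace/measurement CSVs are versioned by their fixed header
(`t_s,intensity,concentration_uM,replicate`; schema v1).

## Membrane-edge subtraction

**Model.** In projection, a protein-decorated vesicle edge is a smooth,
diffuse membrane band along a curved path plus a protein signal that is
periodic in arc length with repeat d. Sampling the edge at interval
Δs = d·m/w (m coprime with w) places any window of w consecutive samples at
phases that sum to zero, so a w-sample rolling mean of tangent-rotated
particle boxes cancels the periodic fundamental exactly while passing the
smooth band. The conventional interval is m = w−1 (20 Å for d = 30 Å,
w = 3); `out_of_phase_interval` verifies the cancellation sum
|Σₖ exp(2πik·Δs/d)|/w < 1e-9 and falls back to the smallest admissible m
otherwise.

**Window length.** w = 3 by default: it is the smallest window that
realizes the 30 → 20 Å phase-cancellation arithmetic, and larger windows
only smooth the membrane estimate further (they still pass DC and the
harmonics at multiples of w). Configurable.

**Harmonics.** A w-sample window passes harmonics of the repeat at
multiples of w (for w = 3 and d = 30 Å: the 10-Å component). The membrane
estimate therefore contains the protein's mean ridge (DC) and those
harmonics; both are removed from the subtracted image along with the band.
This is intrinsic to the approach — the quantity the subtraction is meant
to preserve, and the one scored, is the modulated lattice signal.

**Averaging frame and re-projection.** Boxes are sampled bilinearly on a
grid rotated so the local tangent is horizontal, averaged per edge (windows
truncated at edge ends; edges never mix), rotated back, and blended into an
estimate raster with a separable raised-cosine window (1 over the central
50% of the box, cosine-squared taper to 0 at the border) and an accumulated
weight map. The subtracted image is

    subtracted = micrograph − estimate/max(weight, 1)   where weight > 0.5,

unchanged elsewhere. The 0.5 threshold avoids amplifying fringe pixels
where the taper weight is small. The identity
`micrograph = subtracted + correction` holds pixelwise by construction and
is asserted in the tests; the whole operator is linear in the input raster
for fixed geometry (verified to 1e-6 relative).

**Repeat detection.** `estimate_repeat` samples intensity along arc length
in a band at a fixed normal offset (averaged across the band), subtracts a
running mean whose window equals the upper period bound (this makes the
estimate invariant to constants and slow ramps), zero-pads to ≥ 8× the
profile length, and takes the highest-power period in the search range with
quadratic sub-bin refinement. Confidence is the ratio of the peak power to
the median power over the searched band. On spike-free scenes (membrane +
noise only) this ratio stays below ~16 across seeds while genuine repeats
score in the hundreds, so results below 50 are flagged `low_confidence`;
a constant profile is flagged `no_signal` with period NaN.

**Duplicate removal.** `dedup_coords` is a greedy keep-first scan in stored
row order with the 15-Å minimum-distance criterion, applied per micrograph.
Greedy keep-first is deterministic and idempotent; survivors are pairwise
separated by at least the threshold.

**Evaluation metrics.** With ground truth available, a subtraction is
scored by: membrane attenuation (1 − residual/input membrane mean-square
power inside the band, where the residual is the subtracted image minus the
true protein-plus-noise); lattice retention (after/before ratio of the
arc-length spectral power at the planted repeat frequency along the spike
band); and template correlation gain (mean normalized cross-correlation of
boxes at the true spike coordinates against the mean ground-truth protein
patch, after minus before). For the correlation, boxes and template are
first detrended by removing the along-tangent mean of each row: in the
rotated frame both the membrane band and the protein's mean ridge are
constant along the tangent, so detrending isolates the modulated lattice
component that 2D alignment actually uses. Without it the score is
confounded by the geometric overlap of the band with the template and by
the unavoidable DC removal described above.

## Synthetic scenes

**Edge scenes** emulate the statistical structure the subtraction assumes:
a Gaussian band (amplitude 2, half-width 60 Å, blurred by σ = 20 Å)
following a gently curved cubic path — smooth and aperiodic along the
edge — decorated with anisotropic Gaussian ridges (length 50 Å along the
normal, width 8 Å along the tangent, amplitude 1) centred every d Å of arc
length at a 60-Å normal offset, plus white Gaussian noise. The standard
scene is 1024×1024 at 2.8 Å/px with d = 30 Å, SNR 1 (noise σ equal to the
spike amplitude) and seed 1. The emitted micrograph equals
protein + membrane + noise exactly (same float32 arithmetic), so every
estimator can be scored against a pixelwise decomposition. Not modelled:
projection physics, CTF (the separation logic operates in real space and is
orthogonal to it), structured ice/carbon background, and edge-shape
statistics of real vesicles (curvature is a free parameter, not a claim
about data).

**Tube scenes** render a filament-wrapped membrane tube in projection: two
Gaussian boundary lines whose *outer half-maximum edges* sit exactly D_out
apart (matching the outer-edge measurement convention), and interior
striations — a raised-cosine field of lines at angle φ to the tube axis
with perpendicular spacing s_if. Planted axis vectors mirror the drawn
lines from which orientations are measured. SNR is defined relative to the
striation amplitude (the weakest signal).

**TIRF traces** wrap the coverage simulator with a baseline offset
(uniform monomer binding) and white noise; the noise-free plateau is
baseline + amplitude at full coverage for any concentration.

## Lattice measurements

Plot profiles sample bilinearly at pixel-size spacing, averaged across an
optional perpendicular width. Peak positions for spacing measurements are
refined to sub-sample precision by parabolic interpolation; the default
peak prominence is 0.2 of the profile's dynamic range (raise it to ~0.35
for noisy single images — peaks of real striations carry ~0.7 of the
range). Outer diameter takes the baseline from the outer 10% of samples at
each end, thresholds halfway to the maximum, and interpolates the outermost
crossings linearly. Curvature uses the cylinder convention κ = 2/D_out from
the same half-maximum measurement; whether a given figure plots 1/R or 1/D
is a convention, and this package's choice is stated, not asserted about
external data. Filament orientation is arccos|û·v̂| of the supplied
membrane and filament axis vectors — drawn lines, not automatic tracing.

## Polymerization kinetics

**Hill fit.** F(t) = F₀ + F_max·tⁿ/(t_halfⁿ + tⁿ), fitted by bounded
nonlinear least squares (n ∈ [0.5, 10]); initialization: F₀ from the first
decile, F_max from the last, t_half at the first midpoint crossing, n = 2.
The baseline term absorbs pre-nucleation monomer fluorescence; whether a
given experimental fit includes one is a modelling choice, made explicit
here. Non-convergence is flagged, not raised. The lag time is the intercept
of the tangent at the inflection with the baseline; for the Hill form the
inflection satisfies (t_inf/t_half)ⁿ = (n−1)/(n+1), which is evaluated in
ratio form to stay finite at large n. Fits with n ≤ 1 have no inflection at
t > 0 and report "no lag" (NaN). The growth rate is the OLS slope over
samples whose fit-normalized intensity lies in [0.2, 0.8] (window
configurable); if the fitted plateau extrapolates beyond the data (e.g. a
still-rising ramp) the normalization falls back to the observed range.

**Simulator.** Nuclei arrive as a spatial Poisson process on a square torus
at areal rate J = k_nuc·(C/C_ref)^p and grow as disks at radial speed
v = k_g·C. Coverage is computed exactly (per raster) from each pixel's
earliest cover time min_i(t_i + d_i/v) with toroidal distances, so θ(t) for
all output times costs one sort. Defaults: k_nuc = 0.01 events·µm⁻²·s⁻¹ at
C_ref = 1 µM, k_g = 5 nm·s⁻¹·µM⁻¹, area 25 µm², 512² raster, dt = 2 s —
chosen so that at 0.3–1 µM the characteristic time t* = (3/(πJv²))^(1/3)
falls in the hundreds-to-thousands of seconds, the scale of membrane-
recruitment experiments. A run is rejected when disk growth per step falls
below a quarter pixel (raster too coarse to resolve growth). For
constant-rate nucleation the expected coverage has the exact closed form
θ(t) = 1 − exp(−πJv²t³/3) (Kolmogorov/Johnson–Mehl/Avrami), used as the
simulator's analytic oracle; the mean-field comparison uses a 150-µm²
field and 100 replicates, which brings the Monte-Carlo error of the mean
well inside a 0.02 absolute band.

**Nucleation order vs. measured rate.** The critical nucleus is five
subunits (contacts span i to i+4 along a protofilament), so the nucleation
rate defaults to order p = n_crit = 5 in concentration, while growth is
linear in C. The slope of the linear region of θ(t) scales as (Jv²)^(1/3)
— it mixes nucleation and growth — so with p = 5 that slope would scale as
C^(7/3). Experiments probing the growth step alone (rate ∝ C, log-log
slope 1: no cooperativity) therefore hold the nucleation order at p = 1 so
that Jv² ∝ C³ and the measured rate is proportional to C; the exponent is
an explicit `SimParams` field. The plateau, by contrast, is concentration-
independent under any exponent (full surface coverage) — saturation here
models surface accessibility only, not bulk monomer depletion.

## Problem sizes

The shipped benchmarks run on one CPU in minutes: the standard 1024² scene
for subtraction and repeat recovery (~3 s per pipeline pass), 512² tube
scenes, 256²–512² coverage rasters with 8–100 replicates per experiment.
These sizes were chosen to make the statistical checks decisive (mean-field
error ≪ tolerance) while keeping the full suite fast.

## Limitations

* The subtraction assumes a traced edge path; tracing/picking itself is out
  of scope, as are CTF handling and any 3D treatment.
* Synthetic benchmarks validate the algorithmic logic, not performance on
  real micrographs: real membranes have structured backgrounds, variable
  repeat phase, and non-Gaussian noise that the generators do not emulate.
* The kinetics simulator covers surface saturation only; monomer depletion,
  photobleaching, and spatially resolved patch analysis are not modelled.
* Greedy duplicate removal is order-dependent by design (stored row order),
  matching the usual processing convention; a different ordering can keep a
  different (equally valid) subset.
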