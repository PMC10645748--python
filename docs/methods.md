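# Methods

This note documents the models and procedures implemented in `chanclust`,
the choices made where the underlying methods literature leaves details
open, and what the synthetic-data validation does and does not establish
about real microscope and patch-clamp data.

## Stochastic self-assembly model

Channel clustering in the plasma membrane is modeled as a discrete-time
stochastic process on a 2D binary lattice (one site ≈ one channel
footprint). Per synchronous step, sampled entirely from the occupancy at
the start of the step:

* an occupied site is vacated with probability `p_removal`;
* an empty site with at least one occupied 4-neighbour is occupied with
  probability `p_growth`;
* any other empty site is occupied with probability `p_nucleation`.

Conventions this package fixes (the process itself does not dictate them):
**4-neighbour connectivity** for both growth adjacency and
connected-component labeling; **periodic boundaries**, removing edge
artifacts from steady-state statistics; **synchronous updates**, with a
growth-eligible site using `p_growth` only (growth takes precedence over
nucleation at the same site). Each site sees exactly one candidate event
per step, so occupancy is binary by construction.

Steady state is declared when the relative change between consecutive
500-step moving averages of the occupancy fraction stays below 10⁻³ for 5
consecutive window comparisons; otherwise the run stops at `max_steps`
with a `converged=False` flag. In very sparse regimes (occupancy fractions
of order 10⁻³–10⁻², e.g. `p_n = 10⁻⁴, p_g = 0.01, p_r = 0.05`), the
window-to-window fluctuation of the occupancy fraction is itself 1–4%, so
this criterion does not trigger even though the occupancy mean is
stationary after a few hundred steps; such runs end flagged, and the size
distribution is still well defined and exponential-tailed (log-linear fit
R² ≈ 0.97–0.99 on a 512² lattice). The flag does trigger in denser regimes
(verified at `p_n = 10⁻³, p_g = 0.1, p_r = 0.05`).

Parameter fitting is a grid search: each candidate rate triple is
simulated to steady state with ≥3 replicate seeds, replicate
relative-frequency size distributions are averaged on the union of sizes,
and the candidate minimizing the summed squared difference to the observed
relative frequencies is returned. Relative frequencies make lattices of
different sizes comparable. Because the published fitted rates for the
specific channel variants are not available to this package, validation
is by self-consistency: a simulation's own output distribution selects its
generating parameters on a coarse grid, and heavier-tailed targets select
larger growth probabilities.

An exact oracle backs the update rule: on a 3×3 periodic lattice the full
512×512 transition matrix can be enumerated from the per-site event
probabilities, and the two-step pattern distribution from Monte-Carlo
batches (10⁵ replicates) agrees with the enumeration (χ² test).

## Segmentation and cluster metrics

3D stacks are thresholded at a fixed absolute intensity, labeled with
26-connectivity, and filtered: components must occupy **more than two
voxels** (default `min_voxels = 3`) and have bounding-box extents of at
least 100 nm laterally and 150 nm axially. With the default 0.13 μm
axial step, the axial minimum implies at least two optical planes.
Volumes are voxel counts × voxel volume; centroids are reported in μm.
2D localization maps use 8-connectivity.

Percent membrane occupancy is defined here as the summed
sphere-equivalent cross-sectional area (π·r² with r from V = 4/3·π·r³) of
membrane-overlapping clusters, divided by the membrane area. The source
measurements report "% of surface membrane occupied" without a formula;
this is the simplest geometry-consistent definition and values are capped
at 100%.

Cluster-size histograms use fixed-width bins (defaults 0.02 μm³ for
volumes, 500 nm² for areas) and are fit with `count = A·exp(−size/τ)` by
nonlinear least squares seeded from a log-linear fit. Because the
exponential family is closed under binning, binned fitting introduces no
shape bias; on 10⁴ samples the decay constant is recovered within 5%.

The macro-cluster threshold is `mean − 2·SD` of a reference (wild-type)
volume distribution — 0.06 μm³ for a mean of 0.12 μm³ and SD of 0.03 μm³ —
with classification strict: a cluster is macro iff volume > threshold.
For an exponential volume distribution with mean μ the expected macro
fraction is the tail probability `exp(−threshold/μ)` (≈0.42 at μ = 0.07
μm³), which the classifier reproduces within sampling error. The
equivalent diameter reported for a threshold volume is the sphere formula
`d = (6V/π)^{1/3}`, i.e. ≈486 nm for 0.06 μm³ and ≈612 nm for 0.12 μm³.
Published figures quoting 193 nm and 278 nm for these volumes are not
consistent with the sphere formula (they are closer to diameters of
spheres of ~one-sixteenth the volume); this package reports the formula
value and notes the discrepancy rather than matching the printed numbers.

Localization rendering uses zero-based pixels and half-open physical
bins: a centroid at (100 nm, 100 nm) on a 20 nm/px grid lands in pixel
(5, 5). The confocal-equivalent Gaussian blur replaces each pixel by a
Gaussian-weighted average of its neighbours within a given radius
(default 200 nm); the Gaussian σ is radius/2 so the ±2σ support matches
the stated radius, and periodic boundary handling conserves integrated
intensity to machine precision. Two point groups closer than the blur
radius merge into a single connected blob, emulating how micro-clusters
appear as one macro-cluster at confocal resolution.

## Sparklet idealization, nPs, and coupling

Traces are sampled at 100 Hz. Idealization assigns each frame to the
nearest integer multiple of the quantal amplitude (half-amplitude
thresholds), clipped to a configurable maximum level. At a quantal
signal-to-noise ratio of 5 the per-frame misassignment probability is
2·Φ(−2.5) ≈ 1.2%, so frame-level accuracy exceeds 95% comfortably.
The quantal amplitude must be supplied (the generators know it exactly);
automatic calibration from a multi-Gaussian fit of the amplitude
histogram is not implemented and is a known limitation for uncalibrated
real data.

Site activity is `nPs = Σₖ k·Tₖ / T`, the time-weighted mean number of
open channels (the standard nP_open analogue; the quantity is defined
only verbally in the motivating literature, so this is this package's
operational definition). Sites with nPs strictly above 0.2 are classed
high-activity.

Coupled gating is modeled by a mixture kernel on the joint state of N
two-state channels:

    P = (1 − κ) · P_indep + κ · P_sync

`P_indep` advances each channel independently with per-frame closing
probability β = 1/(mean open time) and opening probability
α = p·β/(1 − p), where p is the stationary open probability; the default
mean open time is 2 frames (20 ms at 100 Hz), configurable. `P_sync`
draws one single-channel transition for a uniformly chosen representative
channel and moves *all* channels to its outcome, so its mass lies
entirely on the all-closed and all-open states. The endpoints realize the
intended semantics exactly: κ = 0 is independent gating (binomial
marginals), κ = 1 is all-or-none gating confined to levels {0, N}.

Because the channels are exchangeable, the aggregate open count k is
itself a Markov chain on {0, …, N} with

    P_ind(k→j) = Σ_m Binom(m; k, 1−β) · Binom(j−m; N−k, α)
    P_sync(k→N) = (k/N)(1−β) + (1−k/N)·α,  P_sync(k→0) = 1 − P_sync(k→N)

Both the simulator and the estimator operate on this aggregate chain
(equivalent in law to per-channel simulation). κ and p are estimated by
maximizing the likelihood of the observed level path (transition counts ×
log kernel, plus the initial-state term) over κ ∈ [0,1] × p ∈ (0, p_max)
with an 11×9 grid start followed by L-BFGS-B refinement. For N = 1 the
two kernels coincide and κ is unidentifiable; the estimate is returned as
NaN with an `identifiable=False` flag. Records shorter than 100 frames
are rejected. Recovery at the study's scale (N = 3, p = 0.1, 2000 frames,
20 seeds) yields mean estimates ≈0.003 / ≈0.41 / 1.000 at κ_true =
0 / 0.4 / 1, and RMSE shrinks with record length.

Per-cell summaries count sparklet sites and stratify nPs by class; cells
with no detectable sites contribute nPs = 0 to the all-site mean, so
silent cells are included rather than dropped.

## Current-density scaling and IV analysis

The in-silico prediction layer assumes the macroscopic current density
scales linearly with the fraction f of functional channels:
`I(V, f) = f · I_ref(V)`, with built-in single-point references at +50 mV
of 7006 pA/pF (male) and 17,293 pA/pF (female) at f = 1. The full
excitation model that produced the references is not reimplemented; the
published 50%, 10% and 1% predictions are consistent with linear scaling
of the printed 100% values, while the published 0.1% values are not
(presumably a nonlinearity internal to the full model) and are therefore
out of scope. Reported values are rounded at report time only: integer
pA/pF at magnitudes ≥100, one decimal below (Python banker's rounding,
matching e.g. 17,293/2 → 8646).

Drug-subtraction computes the blocker-sensitive current as the pointwise
difference of matched pre/post families; IV extraction averages each
step's current over a window (default the final 50 ms of a 500 ms step)
and normalizes by cell capacitance. A liquid-junction-potential offset
(13 mV for K⁺-based solutions, 9.4 mV for Ba²⁺) can be applied to the
voltage axis and is off by default.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistics* the analyses rely on —
exponential cluster volumes, punctate Gaussian spots with
volume-proportional integrated intensity on a 0.13 μm z-step grid,
Poisson shot noise plus Gaussian read noise, quantized gating with known
κ, frame-wise blinking with localization jitter — but not myocyte
morphology (the membrane is an axis-aligned box shell), antibody labeling
density, fluorophore photophysics, or drift. Passing recovery tests
therefore establishes the correctness of the algorithms under the stated
noise models, not the accuracy of any particular biological measurement;
per-cell values from real microscopes (cluster volumes per genotype/sex,
PLA densities, per-cell nPs and κ) are not reproducible from synthetic
data and are not claimed.

## Problem sizes and numerical choices

Validation runs use sizes chosen to make sampling error small relative
to the tested tolerances while keeping each check fast: 10⁴ samples for
distribution-fit recovery, 512² lattices (3000 steps) for steady-state
tail shape, 128² lattices for the 3×3-replicate fitting grid, 10⁵
Monte-Carlo replicates against the exact 3×3 enumeration, and 20 × 2000
frame traces for κ recovery. All generators take a single seed per call;
the pipeline fans one global seed out to per-stage seeds via
`numpy.random.SeedSequence` spawning in a fixed stage order, so any stage
can be rerun in isolation. Degenerate inputs are defined rather than
left to chance: empty populations yield zero metrics with a flagged
undefined mean, non-positive macro thresholds warn, exponential fits
require ≥3 non-empty bins, and non-convergent assembly runs return
flagged results instead of raising.
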