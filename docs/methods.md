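# Methods

## Scope and units

All analyses operate on ordered frames of particle coordinates in an
orthorhombic periodic box.  Internal units are fixed to ångström and
nanosecond; every reader converts on ingest and every report echoes its
units, so lateral diffusion coefficients are always Å²/ns.  Triclinic boxes
are rejected explicitly rather than silently mishandled: all observables
here are lateral (XY) and assume a z-normal bilayer.

## Binding and the dissociation constant

The binding model is two-state.  Per frame, the minimum-image distance is
taken between the centroid of a TG molecule's central glycerol bead(s) and
the nearest particle of a named residue group.  The bound/unbound criterion
is a package decision, since only the dichotomy itself — not a cutoff — is
standard: a hysteresis rule enters the bound state below `cutoff_on` and
leaves above `cutoff_off`, collapsing to a plain threshold when equal.  The
default is 7 Å for both, a coarse-grained bead-contact scale; both cutoffs
are recorded in every output.

The estimator is the frame-count ratio

    K_D = [TG] · N_unbound / N_bound.

[TG] is taken verbatim from configuration (mol% in the shipped scenarios)
and the estimate carries that unit without conversion; no concentration
convention is imposed.  The estimate depends only on counts, hence is
invariant to frame order.

**Uncertainty.**  Frames are serially correlated, so the 95% CI uses a
moving-block bootstrap over contiguous segments.  Block length is 10× the
mean event (dwell) duration, estimated as `n_frames/(n_events+1)`: blocks
must span several correlation times to be approximately exchangeable, and
for a two-state chain the correlation time is the mean dwell.  Shorter
blocks (≈1 dwell) demonstrably undercover.  Fewer than two observed
transitions triggers an unreliable-estimate warning; zero bound frames is a
hard error (K_D unbounded).  Kinetic rate estimation from dwell times is
out of scope.

## Region classification

"Within the complex" versus "bulk membrane" is operationalised as a radial
cylinder criterion in the membrane plane: a molecule is *complex* in a time
window only if its glycerol XY position stays within `r_complex` of the
protein XY centre for **every** frame of the window, *bulk* only if it
stays beyond `r_bulk` (= `r_complex` + 10 Å buffer) throughout, and
*excluded* otherwise.  Whole-window membership is deliberately
conservative: boundary crossers sample both diffusion regimes and would
contaminate either estimate.  When built from a protein selection,
`r_complex` defaults to the maximum radial extent of the protein beads.
Classification is per window (default 100 frames); per-trajectory
assignment is available by passing one whole-trajectory window.

## Diffusion

MSD is averaged over all molecules of a category and all time origins
within each classified window (overlapping origins, every frame), XY
components of unwrapped coordinates only — unwrapping accumulates
minimum-image frame-to-frame displacements, since wrapped coordinates
destroy displacement statistics.  The production implementation uses the
FFT autocorrelation decomposition (S1 − 2·S2) and is held to the O(T²)
double-loop definition at 1e-9 relative tolerance in the tests; lag 0 is
pinned to exactly zero.

D is the ordinary-least-squares slope/4 over a fit window defaulting to
10–50% of the maximum available lag: very short lags are dominated by any
intercept, long lags have few origins and approach the window length.  The
intercept is free; R² and the OLS slope standard error are reported.  The
slope standard error carries no blocking correction for correlated
residuals, a documented limitation — on smooth ensemble-averaged curves it
understates the true uncertainty, so fold-reduction error bars are
indicative only.  Anomalous-diffusion exponents and finite-size
hydrodynamic corrections are out of scope.

## Interaction score

Every (TG bead, protein bead) minimum-image pair contributes
2/(1+e^{k·r}) to the bead's residue, k = 0.5 Å⁻¹ by default.  The kernel's
length unit is an explicit parameter because a nm/Å mix-up changes scores
by orders of magnitude; with Å the kernel decays on ~9 Å, the bead-contact
range.  All beads of each TG molecule enter the sum, not just glycerol.
An optional distance cap at r_c skips far pairs and records the analytic
per-pair tail bound 2·e^{−k·r_c}; the default cap (`default_distance_cap`)
makes that bound < 1e-6.  AA trajectories are mapped to CG beads first via
an unweighted-centroid mapping table (mass weighting optional); profiles
are time averages by default, with a per-frame sum option.

## Lens detection

The underlying coalescence observation is visual, so the rule here is an
explicit artifact definition.  Single-linkage components over TG glycerol
centroids with minimum-image distances, default cutoff 12 Å (CG
first-shell scale), clustered in 3-D because a lens thickens the bilayer
locally (XY mode available).  Labels are deterministic (size-descending,
ties by lowest member index).  The verdict is *phase-separated* when the
largest-cluster fraction exceeds 50% of TG molecules for every frame of
the final 20% of the trajectory; the onset frame is the first frame of the
uninterrupted above-threshold run reaching the end.  All three thresholds
are configurable and echoed in the verdict.

## Tilt angle

θ(t) = arccos(|v·n|/|v|) in degrees, v joining the centroids of the two
residues' particles under the minimum image, n the box z axis unless
overridden.  The unsigned form (0–90°) is default since the observable is
an angle magnitude; a signed variant (0–180°) drops the absolute value.
Which atoms represent a residue is unspecified upstream, so the centroid
of all the residue's particles is used.  A zero-length vector is an error
for that frame rather than a silent NaN.

## Synthetic data: what it emulates, and what it does not

`gen_brownian_trap` realises lateral Brownian motion with per-step
per-axis variance 2·D·dt, D chosen by the particle's region at the step
start — d_trap inside a disk, d_bulk outside, no barrier at the edge, so
particles exchange freely between regimes like TG entering and leaving the
complex.  The shipped study condition uses d_bulk = 1.1 and d_trap = 0.2
Å²/ns (the magnitudes of the two TG diffusion regimes at all-atom
resolution), 500 particles, 2000 frames of 1 ns in a 400×400 Å box with a
60 Å trap.  30% of particles are seeded inside the trap: TG concentrates
in the complex in the phenomenon under study, and the slow region needs
enough whole-window residents for a stable fit.  Both wrapped and
unwrapped coordinates are stored; MSD consumes unwrapped only.

`gen_two_state` realises the bound/unbound chain with per-frame switching
probabilities 1−e^{−k_on·[TG]·dt} and 1−e^{−k_off·dt}, implemented by
alternating geometric dwell draws (exactly the per-frame Bernoulli chain,
at O(transitions) cost) from a stationary start.  The shipped condition —
k_on = 0.1 per-concentration/ns, k_off = 0.05 /ns, [TG] = 0.5 → K_D,true =
0.5 with ~20-frame mean dwells — gives ≈5·10⁴ transitions per 10⁶-frame
run, enough for percent-level K_D recovery while remaining strongly
autocorrelated enough to exercise the block bootstrap.

`gen_toroid` is a deterministic C11 double-ring bead layout standing in
for the toroid: inner-ring protomers carry the four conserved contact
residues at the membrane mid-plane facing the chamber, scaffold residues
displaced vertically/radially, and the lumenal serine pair above; the
outer ring carries generic beads.  TG can be seeded uniformly or clustered
in the chamber annulus.  `gen_planted_lens` switches a known fraction of
TG from a Poisson-disk dispersed layout to a tight grid at a known onset
frame.

None of the generators include inter-particle potentials, membrane
undulations, leaflet structure, or nucleation thermodynamics.  Passing
tests therefore demonstrate that the *estimators* recover known answers
under the statistical structure the analyses assume — not that those
answers are what a force field would produce; on real trajectories the
physics enters through the input coordinates.

## Problem sizes

The validation battery runs the diffusion recovery at 500 × 2000 frames,
the single K_D recovery at 10⁶ frames, bootstrap coverage at 200
replicates of 2·10⁵ frames (coverage is a property of the interval
construction, not of series length), oracle comparisons at ≤200 frames /
≤50 beads / 100 random configurations, and nucleation at 20 seeds — sizes
chosen so the whole battery completes in seconds while every tolerance
stated for it is meaningful.

## Numerical choices and degenerate inputs

* Unwrapping warns when any per-frame minimum-image displacement exceeds
  0.45 of a box edge (sampling too sparse to unwrap reliably; one frame per
  half-box is the hard information limit).
* `classify_bound` with equal cutoffs reduces exactly to thresholding;
  the first frame's threshold test sets the initial state.
* MSD lag 0 is set to exactly zero; OLS fits require ≥3 lag points.
* Cluster labels and report JSON are fully deterministic (sorted keys, no
  timestamps); fixed seeds give bit-identical generator output.
* d_trap = 0 freezes trapped particles (zero-variance steps); k_off = 0
  makes the bound state absorbing.

## Known limitations

No kinetic (k_on/k_off) estimation, no multi-site binding, no
membrane-curvature or local-normal fitting, no lens shape analysis, no
trajectory alignment, and no TPR/PSF topology parsing.  The OLS slope
standard error underestimates uncertainty on autocorrelated MSD curves, as
noted above.
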