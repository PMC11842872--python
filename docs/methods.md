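# Methods

This note records the models implemented in `chromokin`, their assumptions,
the defaults that matter, and the design choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Illumination schemes and tracking

An illumination scheme is an ordered cycle of events, each an exposure, a
camera readout, and an optional dark time (all in seconds); one frame is
recorded per event and its timestamp is the start of the exposure. Built-in
constructors cover the four experimental patterns: continuous (10 ms
exposure + 1.7 ms readout, 11.7 ms frame cycle), time-lapse (501.7 ms frame
cycle, optionally a 4013.6 ms dark time), interlaced time-lapse (ITM,
frames alternating 0.2 s and 4 s dark times), and TACO (ITM-style
classification frames followed by ten continuous frames). TACO comes in a
*long* variant (two long-dark classification frames before the burst) and a
*short* variant (one short dark directly before the burst), because the two
binding classes need the analysis period adjacent to the dark times that
define them.

Track linking is greedy nearest-neighbor, the algorithm class of the
trackers this toolkit mirrors: candidate (localization, track-head) pairs
within the search radius are claimed in order of increasing distance, with
ties broken by the lowest localization index then the lowest track id —
deterministic and, up to that tie-break, invariant to input order within a
frame. Tracks may bridge at most `max_gap_frames` missed frames. Greedy
(not globally optimal) assignment is adequate at the low molecule densities
simulated here; defaults are a 0.8 µm radius for continuous imaging, with
radii always explicit parameters. Coordinates are µm with the origin at the
image corner; frames are 0-based. Jumps spanning bridged gaps are removed
from jump-distance lists and at most the first 10 jumps per track are kept,
so long-lived bound molecules do not dominate pooled distributions.

## Synthetic data

The generator emulates the study conditions the analyses are designed for.
Molecules switch states by a continuous-time Markov chain (free ↔
short-bound, free ↔ long-bound) with exponential waiting times; the
two-class rates can be replaced by a full dissociation spectrum (rate,
event-weight pairs), with events labeled long-bound below 0.1 s⁻¹. Free
molecules move by 2D Brownian steps with a diffusion coefficient drawn per
molecule from the mixture (defaults 0.3/0.3/0.4 at 0.01/0.3/2.5 µm²/s);
bound molecules move with a slow apparent coefficient (default: the
slowest mixture component) representing localization precision and
chromatin motion, not zero. Displacement variance between frames
integrates 2·D·dt over the exact state segments. Motion is confined to a
reflecting nuclear disk (default radius 5 µm, a typical early-embryo
nuclear cross-section).

Photobleaching and tracking loss are merged into a single per-detection
Bernoulli loss (default 0.0025): after each recorded detection the molecule
is removed with probability p. This absorbing convention is exactly the
`(1 − p)^(t/cycle)` attenuation the spectrum inversion assumes, and it
guarantees no post-bleach detections. What the generator does *not*
emulate: pixel-level images and PSFs, nuclear drift, out-of-focus loss, and
density-dependent mislinking — so passing recovery tests demonstrate the
correctness of the estimators under the stated noise model, not robustness
to every artifact of real movies.

Radial placement draws center-border distances from a density proportional
to bias(c)·c (the ring-area measure) by inverse-CDF sampling on a
2048-point grid; a one-grid-cell spillover at sharp bias cutoffs is the
expected discretization.

`simulate_binding_tracks` generates one track per binding *event* (class
mixture over long/short/spot, exponential dwells, bound motion plus
localization noise). This event-level generator, not the whole-movie one,
is the right input for classifier recovery tests: in a full movie a freely
diffusing molecule contributes many single-frame spots, which is precisely
why ITM class fractions are relative quantities.

## Diffusion fitting

The empirical cumulative jump-distance distribution is binned at 1 nm into
747 bins (both configurable) and fit by least squares with
`CDF(r) = Σ Aᵢ (1 − exp(−r²/4Dᵢdt))`, the sum-to-one constraint imposed by
parameterization (m − 1 free amplitudes), D on a log scale with bounds
10⁻⁵–10² µm²/s, and five deterministic initializations spanning the
plausible decades (best RSS kept). No separate localization-error term: the
slowest component absorbs σ². Out-of-focus and 2D-projection biases are
uncorrected; they affect all conditions of a comparison alike. The binned
CDF is fit unweighted; parameter errors instead come from refitting 500
random 80% subsets (resample refits start from the full-data solution,
which is the same basin). Model comparison uses
ΔAIC = (2k₂ + n ln RSS₂) − (2k₃ + n ln RSS₃) with k₂ = 3 (A₁, D₁, D₂) and
k₃ = 5 (A₁, A₂, D₁, D₂, D₃) free parameters after the constraint, and n the
bin count; positive values prefer three components.

## ITM/TACO classification

A track survives a dark time when consecutive detections flank it within
the confinement radius (default: the tracking radius). Classes are
disjoint: long = survived ≥ 2 long dark times (the > 8.2 s threshold is
emergent from the 4 s + frames + 0.2 s pattern, not a parameter); excluded
("grey") = exactly one long dark time; short = ≥ 1 short dark time and no
long one; spot = single detection. Grey tracks enter the denominator of
both fractions but neither numerator. With this counting the two published
denominator conventions coincide (the grey tracks fold into "one long or no
long dark time" on one side and "passed at least one long dark time" on the
other), so no convention flag is needed. Movie-wise fractions aggregate as
mean ± s.d. TACO mobility takes, per qualifying track, the mean jump
distance over its first complete gap-free continuous burst; later bursts
are discarded to avoid overrepresenting long-lived molecules.

## Survival-spectrum inversion

Survival times are (n_detections − 1) × cycle for confined tracks with at
least three detections. Joint inversion of ≥ 2 conditions fits
`S_c(t) = Σᵢ Aᵢ e^(−kᵢt)(1 − p)^(t/c)` on a log-spaced grid of 200 rates
over 10⁻³–10¹ s⁻¹ by nonnegative least squares. Because each condition only
observes events surviving to t_min = 2 cycles, the fit uses the homogeneous
(conditional) form `Σᵢ Aᵢ [B_c(t_j) − Ŝ_c(t_j) B_c(t_min)] = 0` with a
scale anchor on the first condition's observable mass — this treats the
left-censoring exactly while keeping the problem linear in the true event
amplitudes.

Two numerical choices matter and were made after the plain formulation
proved degenerate. First, survival points are weighted by their binomial
standard errors, so the precisely measured early decays dominate. Second, a
small ridge penalty (λ = 1e-4 rows of λI) regularizes the fast tail: a rate
that barely survives to t_min needs an exponentially inflated event
amplitude to explain the same observed mass, and without the penalty the
solver can park almost all amplitude on unobservable grid rates. The ridge
resolves that near-degeneracy toward the smallest consistent amplitudes and
leaves truly unobservable rates at zero; state-weighted residence times are
insensitive to it. Conditions are weighted equally after the per-point
weights; clusters are read as contiguous support regions. Residence
summaries average rates below/above the 0.1 s⁻¹ threshold with
state-amplitude weighting by default (event-weighted and unweighted are
flags), then invert. Errors come from 500 random 80% resamples of the
survival times.

## Equilibrium kinetic model

Site concentrations and dissociation constants are never materialized:
detailed balance gives k*₍on,i₎ = k₍off,i₎ p₍b,i₎/p_f directly from measured
fractions, and k* absorbs the accessible-site concentration. The
facilitated-diffusion search time is N/k*₍on,u₎ + (N − 1)/k₍off,u₎ with
N = 1/Aᵉₛ unspecific trials; the direct route (used when no search
mechanism is established) is 1/k*₍on,s₎. Effective search times scale by
V_nuc/N_mol and are reported relative to a reference stage; volumes and
molecule counts enter only as relative quantities (absolute calibration is
out of scope). Nuclear volumes for round nuclei come from the
cross-section area as a sphere: r = √(area/π), V = (4/3)πr³. Error
propagation is first-order (delta method) with central-difference partials,
inputs treated as independent.

## CBD analysis

Keyframe outlines (first/middle/last frame) are resampled to 64 vertices by
arc length, oriented counterclockwise, and cyclically aligned by minimizing
summed vertex distance (vertex correspondence is otherwise arbitrary);
per-frame outlines are vertex-wise linear interpolations. The CBD of a
track's *initial* position is |p − centroid| / |border − centroid| along the
centroid→point ray, using the outermost boundary crossing (exact for convex
outlines). Values ≤ 1.02 are clamped to 1 (segmentation noise); larger ones
are excluded and counted. Histograms use five equal-width CBD bins, divide
counts by ring area ((i+1)² − i²)/25 of the unit disk, normalize by the
largest bin, and propagate √count errors through the same normalization.
Pooled histograms weight by track, not by movie.

## Loop-extrusion engine

One update (default 4 s, from 400k simulation steps at 100k steps/s)
applies unload → step → load, in that order (the order is a convention;
it affects only single-update edge cases). Unloading is Bernoulli per
extruder, so lifetimes are geometric with mean Δt/p_unload. Each surviving
extruder moves each non-stalled leg outward one bead; a leg stalls when the
next bead is occupied, is a chain end, or is an impermeable CTCF site, and
stalls are permanent for the extruder's lifetime (the common base of two
colliding loops becomes stationary; orientation-dependent permeability is
deliberately not modeled — site orientation is carried as metadata only).
Loading seeds each adjacent bead pair independently with p_load; pairs
touching an occupied bead, a CTCF site, or a chain end are rejected without
retry. p_load is derived from a macroscopic association rate ρ (per Mb per
minute) as ρ × chain-Mb × (Δt/60) / candidate-pairs, so the configured flux
is honored at any resolution. One bead per side per update makes the
extrusion speed emergent: 2 × resolution/Δt = 0.5 kb/s at 1 kb beads.
Runs burn in for three residence times before sampling.

## Contact analysis

The primary backend is an effective-contour surrogate for 3D polymer
dynamics: each sampled configuration defines a graph with backbone edges
and a weight-1 shortcut across each extruder; contact probability is
max(d_eff, 1)^(−1.5) averaged over samples, with d_eff the shortest-path
distance. The −1.5 exponent is the contact scaling of an ideal chain in a
θ-solvent, so a loop-free chain is an exact power law and loops reproduce
the enrichment/insulation signals that extrusion generates in 3D. A
faithful molecular-dynamics treatment at the published scale (10⁵ steps
per second of real time) is not a desk-scale computation; the surrogate
preserves exactly the loop-topology signal the analyses consume. 10 kb
runs use the same engine with remapped units.

P(s) is the mean contact probability per diagonal, pooled into geometric
bins (8 per decade); local slopes are centered finite differences of
log P vs log s after a 3-point moving average. Slope ratios divide
elementwise on a shared s-grid and mask zero denominators.
Observed/expected divides each diagonal by its own mean (self-normalized);
pile-ups average O/E windows (±100 kb, odd bin count, site-centered) over
sites at least one window from the chain ends. The insulation score is the
mean O/E over the two cross-site quadrants; lower means stronger
insulation.

The optional reduced Langevin backend integrates an overdamped bead-spring
chain (Euler–Maruyama, kT = 1, unit friction, dt = 2e-3): harmonic bonds
U = k/2 (r − b)² with the stiff k = 40 that prevents self-crossing through
stretched bonds, Lennard-Jones volume interactions with a soft-core cap at
r = 0.8σ (initial overlaps push apart instead of diverging), and extruder
bonds imposed from lattice snapshots. It aborts with a diagnostic when a
deterministic step displacement exceeds five bond lengths. The θ-solvent
ε/σ/cutoff are exposed as parameters (defaults ε = 0.3, σ = 1, cutoff 2.5
in reduced units); the backend is capped at 2000 beads.

## Problem sizes and tolerances in the tests

Recovery tests run at the sizes the estimators are designed for: 5×10⁴
jumps for diffusion fits (bound-fraction recovery within ±0.03), 10⁴
survival events per condition for spectrum inversion (slow residence time
within 20%; the two conditions' cycle times differ 9-fold, which decouples
the 0.01 s⁻¹ truth from the 0.0025 per-frame loss), 10⁴ points for the
uniform-disk CBD control (χ²), and a 5 Mb chain at 10 kb resolution for the
stage-contrast pile-up (association 0.6 vs 15 per Mb·min, residence 50 vs
100 s). Statistical assertions use fixed seeds; distributional checks use
KS tests for continuous laws and χ² for discrete ones (KS is biased on
discrete data such as geometric lifetimes).

## Known limitations

- ITM class fractions are relative: the full-movie generator shows that
  freely diffusing molecules flood the spot class, so absolute occupancies
  are only recovered from event-level inputs.
- The event spectrum's fast tail (rates ≳ −ln(obs)/t_min) is intrinsically
  unidentifiable from censored survival data; amplitudes there are
  regularized to zero rather than estimated.
- The effective-contour contact model is a topological surrogate: it
  preserves loop-induced shortening exactly but has no excluded volume,
  so absolute contact values are not comparable to experimental maps.
- The lattice engine's permanent-stall rule slightly lowers steady-state
  density relative to a resume-on-vacancy rule at high crowding.
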