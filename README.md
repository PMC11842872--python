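# chromokin

Single-molecule chromatin-binding kinetics and cohesin loop-extrusion
analysis for developing embryos.

Architectural proteins such as cohesin (Rad21) and CTCF shape chromosomes by
binding chromatin and extruding loops. In early embryos their binding
changes rapidly around zygotic genome activation, and the primary readout is
single-particle tracking of HaloTag-labeled molecules under engineered
illumination schemes. `chromokin` implements the complete computational
chain for such experiments, together with a ground-truth synthetic-data
generator so that every stage has a parameter-recovery test without
microscopy data:

- **Illumination schemes and tracking** — frame/dark-time patterns
  (continuous, time-lapse, interlaced ITM, TACO), greedy nearest-neighbor
  track linking with gap bridging, jump-distance extraction.
- **Diffusion-mixture fitting** — the binned cumulative jump-distance
  distribution is fit with a Brownian mixture,
  `CDF(r) = Σᵢ Aᵢ (1 − exp(−r²/4Dᵢ·Δt))`, Σ Aᵢ = 1; the slowest amplitude is
  the bound fraction f_b. Model choice between 2 and 3 components by
  `ΔAIC = (2k₂ + n ln RSS₂) − (2k₃ + n ln RSS₃)`; errors by refitting 500
  random 80% resamples.
- **Binding-class analysis (ITM/TACO)** — tracks surviving engineered dark
  times (0.2 s / 4 s) within a confinement radius are classified spot /
  short / long; class fractions are `N_class / (N_long + N_short + N_spot)`,
  and TACO's continuous bursts measure per-class mobility.
- **Dissociation-rate spectra** — fluorescence survival times from ≥2
  time-lapse conditions are jointly inverted on a log-spaced rate grid
  (10⁻³–10¹ s⁻¹) by weighted nonnegative least squares with the model
  `S_c(t) = Σᵢ Aᵢ e^(−kᵢt) (1−p)^(t/cycle_c)`, decoupling dissociation from
  photobleaching/tracking loss (p = 0.0025 per frame). Event ↔ state
  spectra convert by dividing amplitudes by their rate and renormalizing;
  residence times average rates below/above 0.1 s⁻¹.
- **Equilibrium target-search model** — pseudo-on-rates
  `k*₍on,i₎ = k₍off,i₎ p₍b,i₎ / p_f`, facilitated-diffusion search time
  `τ = N/k*₍on,u₎ + (N−1)/k₍off,u₎` with `N = 1/Aᵉₛ`, the direct route
  `τ = 1/k*₍on,s₎`, effective search times `τ·V_nuc/N_mol` relative to a
  reference stage, and the predicted long-bound fraction
  `p₍b,s₎ = (k*ₛ/kₛ) / (k*ₛ/kₛ + k*ᵤ/kᵤ + 1)`, with delta-method error
  propagation.
- **Radial (CBD) analysis** — center-border distances of track origins
  inside interpolated nuclear outlines, pooled into five ring-area-
  normalized bins with √count errors.
- **Loop-extrusion lattice engine** — stochastic loading, two-sided
  one-bead-per-update stepping (0.5 kb/s at 1 kb beads and 4 s updates),
  stochastic unloading (geometric lifetimes), mutual blocking, impermeable
  CTCF sites from BED intervals, and the 15·√5 ≈ 33.5 nm bead-size mapping.
- **Contact-map analysis** — effective-contour contact maps
  (`P_ij ∝ d_eff(i,j)^−1.5`, shortest path through loop shortcuts), P(s)
  curves and local log-log slopes, between-stage slope ratios, and
  observed/expected pile-ups around CTCF sites; plus an optional reduced
  Langevin bead-spring backend (harmonic bonds k = 40, θ-solvent
  Lennard-Jones).

## Worked example

```python
import numpy as np
import chromokin as ck

# synthetic continuous-imaging jumps: 13% bound + two mobile components
jumps = ck.sample_jumps([(0.13, 0.01), (0.35, 0.3), (0.52, 2.5)],
                        dt=0.0117, n=50_000, seed=1)
fit3 = ck.fit_mixture(jumps, 0.0117, 3)
cmp = ck.compare_models(ck.fit_mixture(jumps, 0.0117, 2), fit3)
print(fit3.amplitudes.round(3), fit3.coefficients.round(3))
print(fit3.bound_fraction, round(cmp.delta_aic, 1))
```

prints

```
[0.13  0.351 0.52 ] [0.01  0.298 2.487]
0.13 4518.4
```

i.e. the three amplitudes and diffusion coefficients (µm²/s) are recovered,
the bound fraction f_b = A₁ = 0.13 matches the simulated truth, and the
positive ΔAIC correctly selects the three-component model. Continuing with
survival-time inversion on two simulated time-lapse conditions (501.7 ms
frame cycle, with and without a 4013.6 ms dark time, truth: 30% of binding
events at 0.01 s⁻¹ and 70% at 1 s⁻¹, per-frame loss 0.0025) yields

```
tau_s = 98.8 s  tau_u = 0.92 s  A^e_s = 0.277
```

— the long-bound residence time (truth 100 s), short-bound residence time
(truth 1 s), and the long-binding event fraction (truth 0.3).

A shell interface mirrors the library
(`chromokin track / simulate-movie / diffusion-fit / itm-classify / taco /
grid-invert / kinetics / cbd / loopsim / contacts / ps / pileup`); see
`chromokin --help`.

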