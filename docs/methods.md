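# Methods

`netcoarse` simulates network-forming gas–liquid phase separation and
measures the observables that identify its coarsening mechanism: the
characteristic length ℓ(t) and its growth exponent, dynamic-scaling
collapses of the structure factor and of chord-length distributions, the
local packing of the dense phase, coarse-grained strain fields, and
transport diagnostics.  This note records the models, the parameter
choices that matter, and what the desk-scale defaults can and cannot show.

## Physical picture

A deep quench of a particle system with attraction (a colloidal suspension
at volume fraction φ = 0.1, or a one-component LJ fluid at ρ = 0.33)
demixes into a space-spanning network of the dense phase threaded by
dilute pores.  Because the dense phase is far below its glass/arrest
temperature while the dilute phase stays fast, the network responds
*elastically* on the coarsening time scale.  Relaxing an elastic
volumetric deformation ε of the network requires transporting a conserved
quantity through the dense phase — solvent (poroelasticity, diffusivity
D_P) for colloids, heat (thermoelasticity, D_T) for a one-component fluid
— so ε obeys a diffusion equation ∂ε/∂t = D∇²ε.  With ℓ the only pattern
length, the relaxation time is τ = ℓ²/D and the coarsening law is
ℓ ~ (Dt)^{1/2}, i.e. ν = 1/2 — much slower than the ν = 1 of ordinary
viscous bicontinuous coarsening.  A dynamically *symmetric* binary
mixture, in which both phases vitrify together, loses the fast/slow
contrast and shows logarithmic-like rather than power-law coarsening.

## Simulators

**MD (`sim_particles`)** — velocity-Verlet LJ dynamics in reduced units
(σ = m = k_B = 1), Nosé–Hoover chains (length 3, damping 0.1 τ) for NVT.
Cut-and-shifted energies at r_c = 2.5σ (forces keep the small cutoff
discontinuity), cell-binned half pair lists with 0.3σ skin rebuilt on a
skin/2 displacement criterion, dt = 0.002 (0.001 during equilibration at
T ≥ 1).  Quenches are instantaneous: one velocity rescale plus a
thermostat retarget.  The symmetric binary mixture uses a species-pair
well-depth table (ε, ε/2).  Two-particle NVE trajectories conserve energy
to < 1e-6 relative over 10⁴ steps; virial pressures were validated
against an O(N²) double-loop oracle to 1e-10 and against the known
zero-pressure FCC density (ρ ≈ 1.09).

**Overdamped colloid stand-in** — zero-noise steepest descent
dR/dt = F/(3πησ), time in units of the drag time τ_d = 3πησ³/ε.  This is
a deliberate *non-hydrodynamic* stand-in for desk-scale 3D colloid
morphology: it reproduces the T = 0 network formation and the dense-phase
packing, but transports no momentum through a solvent, so its coarsening
kinetics and pore-scale geometry are not those of the hydrodynamic system
(see "what the desk scale shows" below).  Colloid runs use r_c = 4σ: the
colloid attraction is long-ranged, and truncating at 2.5σ shifts the
zero-pressure packing fraction down by ≈ 0.04 (tail pressure ≈ −1.1 at
ρ ≈ 1).  Per-step displacements are capped at 0.05σ, which only ever
shortens a downhill move; total energy is monitored and must not rise.

**Packings** — FIRE minimization at fixed density.  For the
pressure-vs-φ scan the force tolerance is 0.05 ε/σ and the virial is
evaluated at r_c = 4 on minima obtained at r_c = 2.5: the measured
pressure moves by < 0.05 between max|F| = 0.1 and 1e-5 and by < 0.002
between the two-cutoff scheme and a full r_c = 4 minimization, while the
crossing slope is dP/dφ ≈ 10², so these shortcuts move the zero crossing
by < 10⁻³.  The φ grid is 0.02 with ≥ 5 seeds per point; the crossing is
interpolated linearly and its seed scatter (± 0.005) dominates the error.

**2D FPD (`sim_fpd2d`)** — incompressible Navier–Stokes on a periodic
grid with the colloids as smooth high-viscosity regions (tanh profiles,
width ξ = one cell, 8 cells per σ, viscosity ratio 50 by default).  LJ
depth from the Reynolds rule Re = ρσ²/(ητ_d) = 0.8.  Time stepping:
explicit advection and variable-viscosity stress *about the mid viscosity*
η₀ = (η_max + η_min)/2, implicit spectral treatment of η₀ and of the
pressure projection; the frozen-coefficient amplification factor of this
split is below one at any viscosity ratio, so dt is limited by advection
and colloid displacement only.  Odd-derivative operators zero the Nyquist
wavenumber (a real field's Nyquist coefficient has no Hermitian partner).
A net body force in the periodic box is balanced by a mean pressure
gradient (the k = 0 force component is removed).  Validation: Taylor–
Green and single-mode decay to 1% at uniform viscosity, spectral
incompressibility to round-off, and single-colloid drag against an
independent steady-Stokes fixed-point solve on the same grid (5%).

## Field analysis

**Coarse-grained density** — ρ_g(r) = Σ_i (2πΔ²)^{-d/2} exp(−|r−R_i|²/2Δ²)
with Δ = σ by default.  The kernel is *normalized*: ρ_g is then a density
estimate (dense phase ≈ 1.0 σ⁻³, gas ≈ 0) and the rich/poor threshold
ρ_th = 1/2 is the half-density contour, which tracks the true interface
of a compact phase.  The unnormalized sum-of-unit-Gaussians variant is
available (`normalized=False`) but fails the mass-balance check: its mean
value at these densities is ≈ 3, so a 1/2 threshold marks nearly all
space as rich.  The mass balance — rich-phase volume fraction ≈ φ/φ_dense
≈ 0.1/0.54 ≈ 0.185 — is asserted in the test suite.

At desk scale the network strands are only ~2σ wide, so the *analysis*
pipeline for the stand-in uses Δ = σ/2: a filter comparable to the strand
width erodes thin strands (rich fraction drops to ≈ 0.12 and pores merge
through the gaps).  The original-scale measurements happen at
ℓ ≈ 15–25σ, where Δ = σ sits far below the feature size; scaling the
filter with the feature size preserves that regime.  This choice is
validated by the mass-balance property, not by any chord observable.

**Structure factor** — S(q) = |ρ_q|²/N from the FFT of the sharp-sphere
density (6/πσ³ inside radius σ/2; grid σ/4 in 3D, σ/8 in 2D), radially
binned at 2π/L.  ⟨q⟩ is the first moment over [2π/L, π/σ]; the upper
cutoff excludes particle-scale correlations, and ℓ = 2π/⟨q⟩ varies by
< 15% for any upper cutoff in [1.2, π] σ⁻¹ at desk scale.  A direct-sum
point-particle variant exists for oracle tests.

**Growth exponent** — guarded log-log least squares on ℓ(t) with two
guards.  Finite-size: ℓ ≤ L/3; a box-doubling study (N = 9000 vs 24000 at
ρ = 0.33) measured the suppression of ℓ at 2% / 4% / 8% for ℓ = L/4, L/3,
L/2, so L/3 costs less than the fit scatter while L/4 discards most of
the desk-scale window.  Initial-transient: ℓ ≥ 1.5 ℓ(0⁺); the data follow
ℓ² = ℓ₀² + Dt with ℓ₀ ≈ 4.5σ (the post-quench pattern scale), so the
apparent log-log slope is 0.5·(1 − (ℓ₀/ℓ)²) and approaches 0.5 from below.
That offset also fixes the box sizing of the 3D experiment: slopes within
0.05 of the asymptote need ℓ > 3ℓ₀ ≈ 13.5σ inside the guard, i.e.
L ≥ 40σ (N = 24000).  The window search keeps the largest contiguous run
of frames with bounded running-exponent drift; a quadratic (curvature)
fit inside the window flags logarithmic-like growth — drift of the local
exponent beyond 0.1 per window and twice its standard error — which is
how the glassy symmetric mixture is distinguished from a true power law.

**Chords** — a chord is the full boundary-to-boundary segment of one
phase through a uniformly sampled point along an isotropic direction,
marched on the mask in half-cell steps with a midpoint correction
(lengths carry one-step uncertainty); rays reaching L are censored.
Full chords (rather than one-sided point-to-boundary distances) are the
standard porous-media chord statistic: their density vanishes below the
local passage width, producing the interior peak of P(ℓ_out), whereas
one-sided distances have maximal density at zero.  On an ideal level-cut
Gaussian-random-field bicontinuous structure at rich fraction 0.185 the
full-chord pore peak sits at 0.82 ℓ, reproducing the expected 0.8 ℓ; the
one-sided variant (available via `one_sided=True`) peaks near 0.2 ℓ.
Note point sampling weights chords by length; this matches the
"randomly chosen points" measurement procedure.

**Voronoi packing** — periodic tessellation via 3^d ghost images (cropped
to a half-box shell; the partition identity Σ V_vor = L^d is asserted on
every call to 1e-8), φ_vor = πσ³/(6V_vor).  The dense-phase packing is
the location of the *rightmost prominent peak* of the smoothed P(φ_vor)
restricted to in-mask particles: in a thin-stranded network most
particles sit on strand surfaces and their cells leak into the pores,
creating a large low-φ_vor hump; the dense-phase packing appears as a
sharp secondary peak near 0.54 that a global mode estimator misses.

**Strain** — displacements unwrapped by accumulated minimum image;
u(r) = Σu_i G(r−R_i)/ΣG with G a Gaussian of width σ centered (by
default) at the later-time positions, void where ΣG < 10⁻³ of its mean;
strain by void-aware central differences; ε = tr ε_αβ.  P(ε) is taken
over non-void, dense-phase grid points and overlaid as (t′/t₀)P vs
t₀ε/t′.  For strictly constant particle velocities this collapse is exact
only with reference-time kernel centering (the default anchor moves with
t′); the oracle tests use that flag.

**Transport** — spectral diffusion solver (exact per-mode decay
e^{−Dk²t}); τ = ℓ²/D bookkeeping; pore-pressure statistics by periodic
connected-component labeling of the pore phase with a
between/within-variance ratio.  D_T is measured by scaling velocities
with √(1 + A cos kx) (A = 0.5, smallest box mode) in an N = 4000, ρ = 1
LJ system prepared by equilibrating at T = 1.0 and quenching to T = 0.3
(at ρ = 1 that state point is below melting, so the preparation is
explicitly a glass quench), then following the cosine mode of the
per-particle kinetic energy under NVE.  About half the imposed amplitude
equilibrates into potential energy within ~1 τ; the diffusive decay
Γ = D_T k² is fitted after that burn-in, on a τ/2 moving average of the
amplitude (a linear filter leaves the rate unchanged), by nonlinear least
squares with an R² quality flag.  Five seeds give D_T ≈ 3.0 ± 0.2.

## What the desk-scale defaults show — and what they do not

All defaults target minutes on one CPU, far below the original
512³-grid/10⁵-particle scale:

* 3D quench (N = 24000, t ≤ 30 τ): the guarded exponent lands at
  ν ≈ 0.44 ± 0.02 — consistent with 1/2 given the residual ℓ₀ offset and
  ~4% finite-size suppression inside the guard, but not a demonstration
  of a full decade of pure power law.
* 2D quench (N = 16000, ρ = 0.40, T = 0.3): the huge box (L = 200σ)
  leaves the guard irrelevant; the transient guard dominates.
* The overdamped stand-in reproduces the *statics* of the network
  (dense-phase Voronoi packing 0.54, zero-pressure packing, mass balance,
  pore/network chord-peak ratio ≈ 4) but not the hydrodynamic
  *pore-scale geometry*: its gradient-descent gel has broad, large pores,
  so the pore-chord peak sits at ≈ 1.3–2 ℓ instead of 0.8 ℓ, and its
  coarsening exponent is far below 1/2.  These are genuine physical
  differences of the stand-in, reported as computed.
* The 2D FPD runs demonstrate solver correctness (drag, decay,
  incompressibility) and pore-pressure heterogeneity on small grids;
  multi-decade hydrodynamic coarsening is out of scope.

The synthetic generators emulate quenched homogeneous initial states with
ideal interactions; they contain no polydispersity, no gravity, no
hydrodynamic interactions in 3D, and no experimental noise, so passing
tests validate the pipeline's internal consistency and its agreement with
closed-form/oracle results, not agreement with any particular experiment.

## Numerical choices and degenerate inputs

Seeds thread through every random stage (RSA placement, Maxwell
velocities, chord rays, jitter) and identical configurations reproduce
bit-identically.  Degenerate cases are explicit errors: overlapping pairs
below 10⁻⁶σ, all-rich/all-poor masks, moment windows with < 3 bins,
exponent fits with < 8 frames, Voronoi with < d+1 particles, non-cubic
spectral grids, triclinic boxes in the readers.  Co-spherical Voronoi
degeneracies are defused by a seeded 10⁻⁹σ jitter.  Histograms over
step-quantized chord lengths snap their bin edges to multiples of the
march step to avoid aliasing spikes.
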