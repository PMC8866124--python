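# Methods

## Two-site exchange model

All kinetic analyses assume a two-site exchange process A ⇌ B between a
major conformation (population p_A = 1 − p_minor) and a minor
conformation (p_minor), with total exchange rate constant
k_ex = k_AB + k_BA and detailed balance k_AB = p_minor·k_ex,
k_BA = p_A·k_ex. p_minor may equal 0.5 exactly: the symmetric case
describes degenerate exchange such as an aromatic ring flip, where the
two "states" are the symmetry-related ring orientations.

Shift differences Δδ are carried in ppm and converted to angular
frequencies with Δω = 2π·Δδ·10⁻⁶·(field·|γ_X/γ_H|); the
gyromagnetic-ratio table (constants.py) is the single authoritative
source for all nuclei and is quoted to at least five significant
digits. Δδ is magnitude-only by default — constant-temperature CPMG
does not determine its sign robustly — and signed values are accepted
where provided.

### CPMG forward models

The authoritative CPMG observable is computed by numerical propagation
of the two-state transverse magnetisation under

    A = [[−R2,0 − k_AB + iΩ_A, k_BA], [k_AB, −R2,0 − k_BA + iΩ_B]]

through the constant-time element (τ — 180° — 2τ — 180° — τ) repeated
N/2 times, with ν_CPMG = N/(2T), τ = T/(2N), ideal instantaneous 180°
pulses modelled as complex conjugation (conjugations occur in pairs, so
the element collapses to the linear map E(τ)·conj(E(2τ))·E(τ)), the
equilibrium initial condition (p_A, p_minor), and
R2eff = −(1/T)·ln(|M_A(T)|/p_A). Only in-phase magnetisation is
treated: the relaxation-compensated experimental schemes justify
ignoring scalar-coupling and cross-correlation pathways at the level of
the fitted model, and ¹H CPMG uses the identical propagator. Both
states share R2,0 per spin per field; a state-specific offset is not
identifiable from these data and is never fitted.

The closed-form route (`carver_richards_*`) evaluates the same
ideal-pulse problem exactly in scalar complex algebra (Sylvester
formula for the 2×2 exponentials, analytic eigendecomposition for the
N/2 matrix power). The historical approximate Carver–Richards
expression was deliberately not used: at small pulse counts (N = 2) in
slow-exchange corners with large minor populations it deviates from
the propagator by several s⁻¹, which would dominate every oracle
comparison. The exact evaluation agrees with the propagator to
~10⁻¹² s⁻¹ while remaining an independent code path (no shared matrix
routines); degenerate eigenvalue pairs fall back to the confluent
limit, and non-finite closed-form values (not observed in practice)
fall back to propagation.

The Luz–Meiboom fast-exchange limit
R_ex = (p_A p_B Δω²/k_ex)(1 − (4ν/k_ex)·tanh(k_ex/4ν)) is provided as
an analytic cross-check; callers are responsible for the k_ex ≫ Δω
regime.

### Rotating-frame relaxation

On-resonance R1ρ is computed from the full 6×6 two-state rotating-frame
evolution matrix (x, y, z magnetisation per state; spin lock ω₁ along
x; state offsets ∓p_B Δω/±p_A Δω around the population-average carrier;
R1 on z, R2,0 on x/y, exchange on all components). The reported rate is
the negated real part of the eigenvalue whose mode carries the largest
share of the initially locked magnetisation (p_A, 0, 0, p_B, 0, 0). The
Trott–Palmer closed form R1ρ = R2 + p_A p_B Δω² k_ex/(ω_A²ω_B²/ω_e² +
k_ex²) (tilt = 90° on resonance) serves as the cross-check; the two
routes agree to ≲0.1% over the experimental spin-lock range for the
wild-type-like parameters.

## Global dispersion fitting

Intensities convert to rates via R2eff = −(1/T)·ln(I/I0). The pooled
standard deviation over technical-replicate pools (per peak, per
ν_CPMG) supplies a single intensity σ for the dataset, propagated to
σ(R2eff) per point by Monte Carlo (both I and I0 perturbed; draws with
non-positive intensities resampled, with an error when more than half
are rejected).

The global fit shares (k_ex, p_minor) across all spins, nuclei and
fields; |Δδ| is per (spin, nucleus) and R2,0 per (spin, nucleus,
field). Because R2,0 enters the evolution matrix as −R2,0·I, the
exchange contribution is exactly additive and each R2,0 has a
weighted-mean closed form; each |Δδ| then reduces to a 1-D
minimisation solved by nested vectorised grid scans (coarse 33-point
scan over a per-nucleus range, then 4-fold refinements). The per-
nucleus search ranges (8 ppm ¹⁵N, 2 ppm ¹H, 4 ppm ¹³C) matter: the SSE
basin width in ppm scales inversely with the gyromagnetic ratio, and
the scan must resolve the global basin because the objective can be
multi-modal in |Δδ| (a slow-exchange false minimum exists at large
shifts). The outer two-parameter problem is minimised by Nelder–Mead
in (log k_ex, logit p_minor) from a multi-start grid
(k_ex ∈ {250, 1000, 2500, 7000, 20000} s⁻¹ ×
p_minor ∈ {0.01, 0.05, 0.15}); the best grid points are polished and
the lowest optimum kept. Points with σ = 0 receive the dataset's
median positive σ. Reduced χ² uses n_points − (2 + n_units +
n_profiles) degrees of freedom.

Parameter uncertainties come from refitting Monte Carlo perturbations
of the R2eff values (parametric bootstrap), warm-started at the point
estimate with looser convergence settings; the reported σ is the s.d.
of the refitted parameters, and an error is raised when fewer than 80%
of refits converge. Calibration measured by simulation: across 200
replicate two-spin, two-field experiments at 2% noise, the generating
k_ex lies within ±1σ of the fit in ≈70% of replicates (nominal 68%).

Exchange detection per spin compares the flat model (R2,0 only)
against a Luz–Meiboom-shaped alternative (amplitude profiled linearly,
k_ex scanned over a log grid) with an F-test at α = 0.05 (default);
AIC values for both models are reported alongside. The simulated
type-I error is ≈0.03 — slightly conservative, as expected when k_ex
is unidentifiable under the null — with power >0.95 for 10 s⁻¹
dispersions at 0.3 s⁻¹ noise.

## Synthetic dispersion datasets

The generators define the study conditions. The kinetic fixtures carry
the published fitted values: wild type k_ex = 2,600 s⁻¹,
p_minor = 0.028; H493A k_ex = 2,830 s⁻¹ with p_minor = 0.05 (the
mutation slightly stabilises the minor state; no number is printed, so
a modest increase over wild type was chosen once); V517A
k_ex = 6,800 s⁻¹ with p_minor = 0.45 (near-inverted populations).
Schedules default to the published experiments: ¹⁵N at 600/850 MHz
(T = 32 ms, ν = 31.25–1,000 Hz), amide ¹H at 600/950 MHz (T = 20 ms,
ν = 50–2,000 Hz), aromatic ¹³C at T = 20 ms, ν = 100–1,000 Hz.
Intensities are I0·exp(−R2eff·T) from the propagator with Gaussian
noise of σ = 0.02·I0 by default (a typical noise level for
well-behaved dispersion data; the source experiments do not print
theirs), two replicate points per profile, and per-spin |Δδ| drawn
uniformly within the observed spans (≤4.7 ppm ¹⁵N, ≤1.1 ppm ¹H), one
spin pinned at each span maximum so span recovery is testable.

Real datasets contain only residues whose peaks survive exchange
broadening. Each spin's |Δδ| is therefore drawn by rejection until its
true (noiseless) intensities stay above a 3σ detection limit at every
scheduled point under the fixture's kinetics. This matters for the
near-inverted V517A fixture, where large-Δδ spins are unmeasurable:
censoring individual noisy points instead (an earlier design) removed
preferentially the most exchange-affected observations and biased the
fitted k_ex low by ~10–20%; conditioning the drawn spins on
measurability — which is how experimental dispersion tables are
actually assembled — leaves the surviving data unbiased. The pinned
span-maximum spin falls back to rejection sampling when the span
itself is unmeasurable (never the case for the wild-type kinetics).

What the generator does not emulate: peak overlap, baseline and
phasing artefacts, off-resonance and pulse-imperfection effects,
temperature instability, and scalar-coupling evolution. Passing
recovery tests therefore demonstrate the correctness and calibration
of the analysis chain under the stated noise model, not robustness to
every experimental pathology.

## Sequence analysis

Size scores are the heavy-atom counts of the 20 side chains (G = 0 …
W = 10), applied at the alignment columns of JIP1-SH3 residues 493,
517 and 541 after retaining only sequences with Tyr/Phe at the 526
column. Sequences with alignment gaps at scored columns are excluded
with a logged reason (this reproduces the exclusion of family members
with long insertions). PCA uses column centering with unit-variance
scaling by default — the webtool used for the original analysis scales
this way for such inputs — with a raw-centering mode available since
the original setting is not stated; components are sign-fixed by
making each component's largest-magnitude loading positive. Group
assignment is 2-means on the first two component scores (20 restarts,
seeded), with group 1 anchored to the JIP1 row so the eclipsed/
staggered semantics are stable under permutation and sign flips.

The planted-family generator writes group-1 rows with the
eclipsed signature (large 493, small 517/541) and group-2 rows with
the staggered signature (small 493, Ile/Leu 517, large 541), all with
Tyr/Phe anchors, over a conserved random background alignment.

## Structure geometry

χ₂ is the Cα–Cβ–Cγ–Cδ1 torsion (IUPAC sign convention, atan2
construction), folded into (−90°, +90°] by the two-fold ring symmetry.
Superposition is Kabsch (SVD with reflection guard); morphing is
superposition followed by per-atom linear Cartesian interpolation over
the shared atom keys — unlike the energy-refined morphing used for the
original trajectory, so pocket-expansion values carry a documented
±15 Å³ tolerance. Glycine substitution removes Cβ and beyond,
bit-preserving backbone coordinates.

Pocket volumes are POVME-style: a cubic grid of spacing δ (default
0.5 Å) snapped to the centre of an inclusion sphere (default radius
8 Å around the target ring centroid — the original inclusion region is
unstated, so it is exposed as configuration); grid points within
(Bondi van der Waals radius + 1.09 Å hydrogen cutoff) of any atom are
deleted; the 6-connected component containing the seed point is kept;
volume = count·δ³. The calculation operates on heavy atoms with the
Bondi radius set — the original protocol added explicit protons before
gridding with the same 1.09 Å cutoff; using heavy-atom radii plus that
cutoff compensates at the sub-cell level and the residual difference
is absorbed into the stated tolerance. A closed pocket (seed point
excluded) raises an error, or reports 0 Å³ inside trajectory profiling
where a closing pocket is a legitimate observation.

The breathing-cage fixture tiles a 6 Å sphere with 600 carbon
pseudo-atoms (Fibonacci lattice; spacing ≈0.9 Å, small enough that the
discrete shell bulges the analytic cavity radius by <2%), giving a
closed cavity of analytically (4/3)π(6 − 1.70 − 1.09)³ ≈ 138.5 Å³; the
open conformation displaces the 30° polar cap outward, creating a
funnel whose volume grows monotonically with the gate displacement.

## Model-free analysis

The spectral density is the standard Lipari–Szabo form with isotropic
overall tumbling; R1, R2 and NOE use the dipolar + CSA expressions at
{0, ω_N, ω_H−ω_N, ω_H, ω_H+ω_N} with N–H bond length 1.02 Å and ¹⁵N
CSA −172 ppm (community defaults; the original supplementary choices
are not visible, and these constants are flagged as such). The fit
shares a single τ_c across residues: τ_c is scanned on a grid and
refined with the fuller {S², τ_e} model per residue (scanning with the
restricted {S²} model alone biases τ_c when internal motion is
present), then per residue the simpler of {S²} and {S², τ_e} is
selected by AIC. Noiseless inputs receive a tiny relative σ floor
(10⁻³·|value|) so model selection still prefers exact models. No
exchange term is included — R_ex belongs to the dispersion analysis.

## Problem sizes and numerical settings

The recovery experiments use 15 spins × 2 nuclei × 2 fields (870
points) at 2% noise with 15–25 Monte Carlo draws for parameter σ;
statistical calibration uses 1,000 null replicates (detection) and 200
replicate experiments of 2 spins × 2 fields with 15 draws (coverage);
pocket grids use δ = 0.5 Å with δ ∈ {1, 0.5, 0.25} for convergence
checks. These sizes were chosen to estimate each quantity to well
within its acceptance band. Nelder–Mead tolerances are 10⁻⁴ (xatol,
log/logit scale) for primary fits and 10⁻³ for warm-started Monte
Carlo refits; the |Δδ| scan resolves ~0.004 ppm (¹⁵N scale) at primary
settings.

## Known limitations

* Off-resonance R1ρ, multi-site exchange and pulse imperfections are
  out of scope; the R1ρ carrier is assumed exactly on the
  population-average shift.
* In the fast-exchange regime (V517A-like), p_minor and |Δδ| are
  intrinsically degenerate (only p_A p_B Δω² and k_ex are well
  determined); k_ex recovery is accurate but the fitted p_minor for
  such fixtures is not individually meaningful.
* The morph is not energy-refined; interpolated frames can contain
  sterically unreasonable geometries, which is acceptable for void-
  volume profiling but not for energetic interpretation.
* Model selection for model-free fitting covers only {S²} and
  {S², τ_e}; anisotropic diffusion and slower internal modes are not
  modelled.
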