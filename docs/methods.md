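# Methods

## Signal model

The package models the direction-averaged (powder) pulsed-gradient
spin-echo signal of cortical tissue as a three-compartment mixture:
sticks (neurites), spheres (somas) and Gaussian extra-cellular water.
All compartments are impermeable (no inter-compartment exchange) and
relaxation weighting is ignored — both are simplifications, acceptable
at a single echo time but known to bias fractions when exchange is fast
relative to the diffusion time.

Units throughout: b-values in s/mm², diffusivities in μm²/ms, gradient
amplitudes in mT/m, pulse timings (δ, Δ) in ms, radii in μm. Conversions
are centralized; the gyromagnetic ratio is γ = 2.6751×10⁸ rad s⁻¹ T⁻¹,
and b = γ²G²δ²(Δ − δ/3).

**Stick.** Powder average `√(π/(4bD))·erf(√(bD))`, a function of the
product bD only. Verified against polar-angle quadrature to 1e-6.

**Sphere.** Gaussian-phase-distribution (GPD) series of
Murday–Cotts/Balinov for a reflecting sphere, using the eigenvalues
`a_m` of `j₁′(a) = 0` found by bracketed root-finding (a₁ ≈ 2.0816).
The series is truncated at 20 roots with a relative-term tolerance of
1e-8 (a warning is raised if the last term is still large); roots are
computed once and cached. The implementation was verified against an
independent double-quadrature of the phase variance using the sphere
position autocorrelation (agreement ~1e-5), so any residual deviation
from ground truth is the GPD approximation itself, not the series.

**Ball / zeppelin.** `exp(−bD)` and
`exp(−bD⊥)·√(π/(4bΔD))·erf(√(bΔD))` with ΔD = D∥ − D⊥; the zeppelin
reduces continuously to ball (ΔD = 0) and stick (D⊥ = 0).

**Rician noise.** `S → √((S+ε₁)² + ε₂²)` with ε ~ N(0, σ²) and
σ = S(b=0)/SNR. Noise is applied per measurement (per direction) before
spherical averaging, as a scanner produces it; the per-shell effective
SNR therefore grows with the direction count, which is deliberate and
mirrors how multi-direction protocols actually behave.

## Acquisition protocols

The clinical protocol is b = 0/700/1000/2000/3000 s/mm² with
12/6/20/45/66 measurements, δ/Δ = 19/36 ms, peak gradient ≈ 63 mT/m
(within an 80 mT/m system). The high-gradient research protocol that
the resolution study contrasts it with is bundled as a *representative*
scheme — δ = 8 ms, Δ = 29 ms, shells 0/1000/2000/3000/5000/7000/10000
s/mm² with 12/12/32/48/60/60/60 directions, peak gradient ≈ 288 mT/m —
because what drives radius resolvability is the b-range and gradient
ceiling, not the exact direction layout. Δ = 29 ms is the shortest
round value at which the top shell is reachable under the 300 mT/m cap
with δ = 8 ms. Any real scheme file can be supplied instead
(`gx gy gz |G|(T/m) Δ(s) δ(s) TE(s)` per line). Directions are
electrostatic-repulsion point sets (Fibonacci initialization, antipodal
Coulomb relaxation), deterministic; downstream powder averages are
insensitive to the exact layout. Shell grouping uses a 50 s/mm²
b-tolerance, which separates all bundled shells unambiguously.

## Dictionary fit

The dictionary holds 13 atoms: 1 stick (D = 2.4), 9 spheres (D = 3.0,
radii equally spaced 1.5–12 μm) and 3 balls (D ∈ {0.4, 1.6, 3.0}),
evaluated on the scheme's shell centers; the b0 row is all ones. The
voxel problem is Tikhonov-regularized NNLS on ℓ2-normalized columns
(weights un-scaled afterwards); normalization makes the active-set
solver select atoms by direction, so a noiseless single-atom signal is
always recovered as that atom. The default λ = 1e-3 (relative to the
normalized dictionary's spectral norm) stabilizes the under-determined
clinical fit (5 equations, 13 unknowns) without visibly perturbing
well-posed fits; λ and the radius grid are configurable. Negative
powder values (possible after noise at high b) are clamped to zero with
a warning. `f_soma` is defined as the sphere-class share of the *total*
weight, and `R̂` as the weight-weighted mean sphere radius, undefined
(NaN) when the total sphere weight is below 1e-6. Fractions are scale
invariant by construction.

Because several distinct non-negative weight vectors can reproduce the
same five powder means exactly (the stick column, for instance, is
numerically representable by sphere+ball mixtures), individual
fractions from a clinical protocol should be read as regularized point
estimates of a degenerate problem. Quantifying the practical
consequences of that degeneracy is the purpose of the resolution
experiment, not something the fit itself can remove.

## Monte-Carlo oracle

The random walker initializes spins uniformly in the sphere, steps with
per-axis Gaussian increments, reflects specularly at the wall
(sub-step splitting, iterated for multiple crossings), and accumulates
phase `φ = γ∫G(t)x(t)dt` with the signed pulse profile handled by exact
per-step overlap weights. The signal is `|⟨e^{iφ}⟩|` with a standard
error from the across-walker variance. The time step adapts to
`dt ≤ R²/(150·D)` (rms step ≤ R/5); a convergence study showed this
removes the discretization bias that a fixed δ/20 step leaves at small
radii. Defaults for oracle use: 10⁵ walkers (SE ≲ 0.003 of S₀).
Trajectories are reused across shells sharing (δ, Δ) since they do not
depend on G. Sticks are simulated as 1-D free diffusion along
per-walker random orientations.

Agreement between the GPD sphere signal and the converged walker is
excellent in the motional-narrowing and moderate-attenuation regimes
(differences within ~3 MC standard errors, i.e. ≲0.005 of S₀), but the
Gaussian-phase assumption genuinely breaks at strong dephasing: at
R = 12 μm on the clinical b = 3000 shell the GPD value exceeds the MC
ground truth by ≈0.037 of S₀, and similar 0.01–0.05 gaps appear at
R = 8–12 μm on the high-b research shells. This is the documented
accuracy envelope of GPD-based soma models, inherited by the fit: the
dictionary is mildly optimistic about large-soma attenuation at high b.

## Resolution experiment

Study conditions: ground-truth radii 1–15 μm (1 μm step), sphere signal
fractions 10–100 % (10-point step), SNR 50, 100 Rician repetitions per
cell, analytic substrate signals (sticks/tensors receive a fresh random
orientation each repetition), intra-sphere diffusivity fixed at
3.0 μm²/ms to match the dictionary. Two scenarios: `intra`
(sphere + stick remainder) and `intra_extra` (sphere and stick 1:1 plus
an extra-cellular tensor remainder, so fractions are capped at 50 %);
the tensor eigenvalues default to (2.4, 0.8) μm²/ms. Each cell records
the median fitted radius over repetitions (median, not mean, for
robustness to the Rician floor) and is classified acceptable when
|median R̂ − R_GT| ≤ τ with τ = 2 μm (≈1.5 dictionary grid steps — the
"acceptable error" band of the classification maps).

Fixing the substrate diffusivity to the dictionary's value removes
model mismatch as a confounder, so these grids isolate the
protocol-plus-noise contribution to radius error; sweeping the
substrate diffusivity away from 3.0 (supported via the config) degrades
recovery substantially and is the main reason real-world thresholds are
worse than the matched-model ones.

The radius-recovery threshold at a fraction is the smallest grid radius
from which *every larger representable radius* stays acceptable; the
scan is bounded by the largest dictionary atom (12 μm) because ground
truths beyond it are structurally unidentifiable — at R_GT = 15 μm the
best achievable error is already −3 μm. Exported grids still cover the
full 1–15 μm range. The fraction-recovery threshold at a radius is the
smallest acceptable grid fraction; note that at very low sphere
fractions the fitted radius is nearly independent of ground truth
(≈9–11 μm for these protocols), so an isolated acceptable cell near the
bias zero-crossing reflects that prior, not genuine sensitivity — read
the fraction thresholds together with the error maps.

## Synthetic cohort and statistics

The generator emulates a 235-subject study (80 healthy controls, 98
relapsing–remitting, 57 progressive MS): Gaussian whole-cortex soma
fractions (HC 0.34 ± 0.01, MS 0.33 ± 0.02), inner/outer layer offsets
(outer positive, largest in progressive MS; inner negative in MS —
directions reported by the study, magnitudes chosen small and
configurable at 0.005–0.01), Poisson lesion counts (~7 per patient, 7 %
subpial), a per-patient random intercept (SD 0.01) plus lesion-level
noise (SD 0.02) on lesion/perilesion soma fractions, a +0.03 subpial
Δf_soma effect in RRMS only, latent-variable qMRI draws targeting
correlations of −0.5 (qT1) and +0.5 (MTsat), and
`sNfL_z = 0.5 + 0.334·(WM volume/10 cl) + 0.738·(Δf_soma/5 points) + N(0,1)`.
WM lesion volumes are Gamma(2, 2.5) cl. The generator emulates the
*effect structure*, not the imaging chain: no spatial maps, no
segmentation error, no scanner drift — so passing recovery tests show
the statistical stages are correctly calibrated and sensitive at these
effect sizes, not that the MRI pipeline is unbiased on real data.

Stages: Welch's unequal-variance t-test (two-tailed) for the
whole-cortex comparison; a random-intercept-per-patient linear mixed
model (ML by default, REML optional) of lesion − perilesion Δf_soma on
age, sex, treatment and lesion type, falling back to OLS when the
random-intercept variance collapses to the boundary (where the two
coincide); Pearson correlations with t-based p-values; and an OLS sNfL
model (f_soma per 5 points, WM volume per 10 cl, subtype, treatment)
reporting adjusted R² with and without f_soma and a χ²(1)
likelihood-ratio p for the nested pair. The vertex-wise surface
analysis of the original design is out of scope (external tooling);
inner/outer-layer ROI summaries stand in for it.

## Numerical and testing choices

Degenerate inputs raise early: timing violations (Δ < δ), fraction sums
≠ 1, all-zero powder vectors, single-shell schemes, zero-variance
correlation inputs, collinear sNfL designs (condition number > 1e8).
Seeds propagate explicitly everywhere; the CLI derives per-stage child
seeds from one global seed by hashing the stage name, so stages are
independently reproducible. Null-calibration tests (type-I error of the
Welch test and of the lesion-type contrast, 500 replicates against the
binomial 95 % band around α = 0.05) run on a reduced 80-subject cohort
with ~5 lesions per patient — the calibration property is
size-independent and this keeps the suite fast. Parameter-recovery
tests use 200 replicates at the study's sNfL sample size (n = 113).

## Known limitations

* No inter-compartment exchange, relaxation weighting, or soma radius
  *distributions* (a single weighted-mean radius per voxel).
* GPD accuracy degrades at strong dephasing (large R, high b); see the
  Monte-Carlo comparison above.
* The bundled research protocol is representative, not the original
  acquisition scheme; thresholds under it characterize the b-range and
  gradient class, not a specific scanner.
* Matched substrate/dictionary diffusivity makes the default resolution
  grids a best case; real tissue adds model mismatch.
* The cohort generator reproduces reported effect directions and the
  two printed sNfL slopes; unreported magnitudes (layer offsets, qMRI
  correlation strengths, intercepts, noise SDs) are package choices
  exposed in the config, and tests assert recovery of whatever the
  config encodes.
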