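# sandilite

Soma And Neurite Density Imaging (SANDI) estimates the fraction of the
diffusion-MRI signal arising from cell bodies (somas), neurites, and
extra-cellular water — a non-invasive, indirect marker of tissue
*cellularity*. It was developed for research scanners with very strong
diffusion gradients (300 mT/m); `sandilite` implements a simplified,
dictionary-based variant of the model usable on clinical 3T systems
(80 mT/m), together with the simulation machinery needed to quantify
what such a protocol can and cannot resolve. The intended users are
researchers studying cortical grey-matter microstructure (e.g. cortical
pathology in multiple sclerosis) who need soma-fraction maps from
clinical multi-shell data plus an honest account of their resolution
limits.

## The model

The direction-averaged (powder) PGSE signal per b-shell is decomposed as

    S̄(b)/S₀ = f_neurite · A_stick(b; D_in)
             + f_soma    · A_sphere(G, δ, Δ; R_s, D_is)
             + f_extra   · A_ball(b; D_ec)

with

* `A_stick(b, D) = √(π/(4bD)) · erf(√(bD))` — impermeable zero-radius
  cylinders (neurites), direction-averaged;
* `A_sphere` — restricted diffusion in a reflecting sphere of radius
  `R_s` (cell bodies), evaluated with the Gaussian-phase-distribution
  (Murday–Cotts) series over the sphere eigenmodes `a_m` (roots of
  `j₁′(a) = 0`, `a₁ ≈ 2.0816`);
* `A_ball = exp(−b·D_ec)` — isotropic Gaussian extra-cellular water
  (an axially symmetric "zeppelin" tensor is also available).

Fitting follows the AMICO approach: the nonlinear model is linearized
into a dictionary of 13 atoms — one stick (`D_in = 2.4 μm²/ms`), nine
spheres (`D_is = 3.0 μm²/ms`, radii equally spaced 1.5–12 μm), three
balls (`D_ec ∈ {0.4, 1.6, 3.0} μm²/ms`) — and each voxel solves

    min_{w ≥ 0} ‖A·w − s‖² + λ²‖w‖²

by non-negative least squares. `f_soma` is the sphere-class share of
the total weight; the soma-radius estimate `R̂` is the weight-weighted
mean sphere radius. A Monte-Carlo random-walk simulator (uniform
initialization, specular reflection at the sphere wall, phase
`φ = γ∫G(t)·x(t)dt`) provides an independent oracle for the analytic
sphere signal, and a resolution experiment maps median radius error over
a radius × sphere-fraction grid for a clinical protocol
(b = 0/700/1000/2000/3000 s/mm², δ/Δ = 19/36 ms) versus a
high-gradient research protocol (b up to 10000 s/mm²).

The package also ships a synthetic patient/control cohort generator and
the downstream statistics of a cortical MS study: Welch's test for the
whole-cortex group comparison, a random-intercept mixed model for
lesion/perilesion Δf_soma contrasts, Pearson correlations against
quantitative T1 and MTsat, and the serum-neurofilament (sNfL) linear
model with a nested likelihood-ratio comparison.

## Worked example

Synthesize a noisy clinical-protocol acquisition of a substrate that is
half spheres (R = 8 μm), half sticks, then fit it:

```python
from sandilite import (prisma_protocol, NoiseModel, SandiFitter,
                       spherical_mean)
from sandilite.resolution import make_substrate
from sandilite.substrate import simulate_substrate_signal

scheme = prisma_protocol()                      # 149 measurements, 5 shells
substrate = make_substrate("intra", R_GT=8.0, f_sphere=0.5)
signal = simulate_substrate_signal(substrate, scheme, NoiseModel(snr=50),
                                   seed=7)
powder = spherical_mean(signal, scheme)         # 5 per-shell means

fitter = SandiFitter(scheme=scheme).fit()       # builds the 13-atom dictionary
f_soma, f_neurite, f_extra, r_hat, rmse = fitter.transform(powder[None, :])[0]
print(f"f_soma = {f_soma:.3f}, R_hat = {r_hat:.2f} um, rmse = {rmse:.2e}")
```

prints

```
f_soma = 0.747, R_hat = 8.07 um, rmse = 1.09e-03
```

The fitted radius lands on the true 8 μm, while `f_soma` overshoots the
ground-truth 0.5: with only five shells at clinical gradient strengths
the 13-atom inverse problem is under-determined, and stick signal is
partly absorbed by sphere and ball atoms. This degeneracy is exactly
what the resolution experiment quantifies — run it from the shell:

```sh
sandilite resolution-map --protocol prisma --scenario intra --seed 1 \
    --out-dir results/prisma_intra
```

which writes the long-format grid CSV, a diverging heatmap
(red = radius overestimated, blue = underestimated, light = within the
τ = 2 μm acceptable band), per-fraction radius-recovery thresholds, and
a provenance sidecar. `sandilite fit` produces NIfTI parameter maps
from a 4D DWI + bval/bvec; `sandilite cohort-sim` / `cohort-analyze`
generate and analyze the synthetic cohort.

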