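# Methods

## Signal model

Every voxel is modelled as a two-compartment intravoxel incoherent
motion (IVIM) system on top of an anisotropic diffusion tensor:

S(b, g) = S₀ · [(1 − f) · exp(−b · gᵀDg) + f · exp(−b · D\*)]

* **D** — symmetric 3×3 diffusion tensor, mm²/s; eigenvalues stored in
  descending order (λ₁ the fibre-axis diffusivity in muscle).
* **f** — signal perfusion fraction, unitless, 0 ≤ f < 1.
* **D\*** — pseudo-diffusion coefficient of the microvascular
  compartment, mm²/s, assumed isotropic and an order of magnitude larger
  than tissue diffusivities.

MD is the arithmetic mean of the eigenvalues and FA the usual normalised
eigenvalue dispersion, √(3/2)·√(Σ(λᵢ−MD)²/Σλᵢ²). All diffusivities are
carried internally in mm²/s; only the reporting layer (`ivimdti.roi`)
converts to the conventional 10⁻³ mm²/s. No T2 relaxation or anisotropic
pseudo-diffusion is modelled.

## Synthetic studies

The generator emulates a two-thigh axial acquisition: two cylindrical
"legs" on a 3D grid (default 32×32×8), an ellipsoidal injured region in
the left leg (default in-plane semi-axes 4 voxels, axially up to 14
slices, clipped to the grid) and its mirror image in the right leg as the
contralateral healthy control. Default tissue parameters are the group
means and between-subject SDs of acute hamstring injury cohorts at
baseline:

| tissue  | λ₁, λ₂, λ₃ (10⁻³ mm²/s)          | f           | D\* (10⁻³ mm²/s) |
|---------|----------------------------------|-------------|------------------|
| injured | 2.19±0.14, 1.73±0.15, 1.48±0.15  | 0.06 ± 0.02 | 30 |
| healthy | 2.03±0.14, 1.56±0.09, 1.34±0.10  | 0.06 ± 0.02 | 30 |

D\* is not a reported outcome in the muscle literature it emulates
(excluded for its high uncertainty); 30×10⁻³ mm²/s sits mid-range of
published skeletal-muscle IVIM values and is configurable. Within an ROI,
eigenvalues are jittered voxel-wise with a 2% coefficient of variation
and fibre orientations scatter with 10° SD around the leg axis — enough
texture that ROI averaging is non-trivial without dominating recovery.
Cohorts draw per-subject tissue means from the between-subject Gaussians
(eigenvalue order re-enforced, f clipped to [0, 0.39]).

The acquisition scheme follows the emulated protocol: b = 0 (×8), 5, 10,
20, 50, 100 (×3 each), 200 (×10), 400 (×10), 600 s/mm² (×12) — 55
measurements, 32 of them at b ≥ 200. Directions per shell are spherical
Fibonacci point sets symmetrised into unit-norm tight frames
(Σᵢ gᵢgᵢᵀ = n/3·I; for n = 3 the nearest orthonormal triplet). Balanced
sets mirror how real gradient tables are designed and give the exact
identity mean(gᵀDg) = MD per shell, which keeps direction-averaged fits
consistent (see below).

Noise is Rician — √((S+n₁)² + n₂²) with independent zero-mean Gaussians —
with spatially constant σ = S₀/SNR per study, the simplest model
consistent with one reported SNR per muscle. The emulated studies report
SNR ≈ 68 in injured and ≈ 45 in healthy muscle at baseline; the simulator
defaults to the conservative 45 globally but accepts any value
(∞ = noise-free). **Not** emulated: anatomy, fat signal and fat
suppression, motion/eddy artefacts, multiband slice leakage, spatially
varying noise, registration errors. Passing tests therefore demonstrate
correctness of the estimators under the stated statistical model, not
robustness to those confounds.

## Fitting

**SNR QC.** SNR at b = 0 is the ratio of the mask-mean b=0 signal to the
mask-mean per-voxel SD across the eight b=0 repeats, with the Gaussian
small-sample factor c₄(n) unbiasing the SD. Noise-free data returns an
∞ sentinel. Studies with SNR < 20 (strict) are flagged for exclusion;
the flag is recorded on every result rather than raised, so QC stays
inspectable.

**Full fit.** Stage A fits S₀[(1−f)e^(−bD) + f e^(−bD\*)] to the
direction- and mask-averaged per-shell signal by bounded trust-region
least squares; stage B repeats the fit per voxel with D\* frozen at the
stage-A value; stage C subtracts S₀,IVIM·f·e^(−bD\*) element-wise and
fits S₀·exp(−b·gᵀDg) (7 parameters) to the corrected signal over all 55
measurements.

**High-b fit.** Measurements with b < 200 s/mm² are discarded (b = 200,
400, 600 remain; 32 directions) and the 7-parameter tensor fit is applied
directly; S₀ is extrapolated by the fit. Threshold 0 degenerates into an
uncorrected all-b fit, which is how the package exposes the perfusion
bias the corrections remove.

**Direction averaging.** The IVIM stages operate on per-shell direction
averages. The default is the *geometric* (log-domain) mean: for a
balanced direction set the tensor compartment then averages to exactly
exp(−b·MD), so the biexponential model is exact for anisotropic voxels
up to a second-order mixture term. The arithmetic mean (available as
`FitConfig(shell_average="arithmetic")`) adds Jensen curvature of order
b²·Var(gᵀDg)/2 that a biexponential fit absorbs into f (≈ +0.003 at
muscle anisotropy) and propagates into ~1% MD error even without noise;
the geometric default reduces noise-free recovery error to ≲ 0.04% in MD
and ~10⁻⁴ in f. At SNR ≥ 20 the log-domain noise bias is negligible
relative to these gains.

**Numerics.** Bounds bracket reported muscle values with wide margins:
f ∈ [0, 0.4], D ∈ [0.1, 4]×10⁻³, D\* ∈ [3, 300]×10⁻³ mm²/s;
initialisation f = 0.05, D = 1.7×10⁻³, D\* = 30×10⁻³, S₀ = max b=0
signal. The bounded stages use `scipy.optimize.least_squares` (trf) with
analytic Jacobians, step tolerance 10⁻¹⁰, gradient tolerance 10⁻¹⁴ (so
boundary solutions such as f = 0 resolve sharply) and at most 500
evaluations. The tensor fit is unconstrained Levenberg–Marquardt with an
analytic Jacobian, initialised from the signal-weighted log-linear
estimate — which guarantees the nonlinear fit never worsens the
log-linear objective. The tensor is not forced positive-definite:
negative eigenvalues are flagged in QC, and FA is computed from the raw
eigenvalues rather than clamped, preserving information. Degenerate
(all-zero) voxels yield flagged NaNs instead of aborting a study;
per-voxel non-convergence is flagged, not fatal. An unweighted residual
is the default for the tensor stage; signal-weighted residuals are a
config option.

**Open choices resolved.** The stage-A averaging domain ("mean data of
both legs") is exposed as a mask parameter and defaults to the union of
the muscle masks. Measurement order never matters: permuting the scheme
and data together changes diffusivity maps by < 10⁻¹⁰ (FA, passing
through an eigendecomposition, by < 10⁻⁸).

## ROI analysis and statistics

ROI values are arithmetic means of the per-voxel parameter maps over a
segmentation mask (NaN-flagged voxels excluded and counted; a warning
fires past 50%), reported in 10⁻³ mm²/s. Sensitivity to injury is
Δ = injured − healthy per subject, method and parameter; Δ is
antisymmetric and translation-invariant by construction. Mask extent is
caller-controlled — shrinking or growing the mask makes the averaging
dilution of focal injuries directly testable.

Method agreement is unweighted OLS of method-2 on method-1 ROI means,
one point per muscle, injured and healthy regressed separately. Bands
are evaluated best-first: excellent (0.9 ≤ slope ≤ 1.1, R² > 0.9), good
(0.8 ≤ slope ≤ 1.2, R² > 0.7), moderate (0.7 ≤ slope ≤ 1.3, R² > 0.5),
else poor; outer bounds are closed. The nesting makes the label total
and monotone in R².

Paired comparisons use the Wilcoxon signed-rank test: zero differences
dropped (classical rule, recorded in the output), midranks for ties,
W = min(W⁺, W⁻), exact null distribution (dynamic programming over
doubled midranks) for up to 25 effective pairs, and a continuity- and
tie-corrected normal approximation beyond. Two-sided exact
p = P(W⁺ ≤ w) + P(W⁺ ≥ T − w). α = 0.05 per test with no multiplicity
correction, matching how such cohorts are conventionally analysed.

## Problem sizes

Single-study recovery checks run on the full default grid (32×32×8,
~270 voxels per ROI). Monte-Carlo suites (cohort agreement across seeds,
bias curves) use a reduced 16×16×6 grid with ~30 voxels per ROI, and the
type-I-error study of the f-test draws subject-level parameters directly
from the between-subject model (1000 replicates of 14 subjects) — the
scale at which that test operates. 14 subjects per replicate was chosen
from the exact null distribution so the discrete test's achievable size
(0.0494) sits closest to the nominal 0.05.

## Known limitations

* The perfusion compartment is simulated and fitted as isotropic; any
  real-world anisotropy of D\* is out of scope.
* The simulator's noise and anatomy are idealised (see above); SNR
  calibration and recovery results transfer to real data only insofar as
  denoising/registration deliver comparable effective SNR.
* The high-b method inherits a small residual perfusion signal
  (f·e^(−200·D\*) ≈ 1.5×10⁻⁴ at defaults) — negligible for muscle but
  not for high-f organs.
* Segmentation is geometric (ellipsoids), not anatomical; no automatic
  segmentation or histogram analysis is provided.
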