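# ivimdti

IVIM-corrected diffusion tensor imaging (DTI) of skeletal muscle:
simulation of multi-shell diffusion-weighted studies of injured and
healthy muscle, the two fitting strategies used when accelerating such
protocols, ROI-level sensitivity measures, and the statistics that
compare them.

## The problem

Diffusion tensor imaging quantifies water mobility in muscle through the
eigenvalues λ₁ ≥ λ₂ ≥ λ₃ of a per-voxel tensor **D**, summarised as the
mean diffusivity MD = (λ₁+λ₂+λ₃)/3 and the fractional anisotropy
FA = √(3/2)·√(Σᵢ(λᵢ−MD)²/Σᵢλᵢ²). At low diffusion weightings (b-values),
microvascular perfusion adds a fast pseudo-random signal decay; ignoring
it biases the tensor estimates upward. The intravoxel incoherent motion
(IVIM) model separates the two compartments:

    S(b, g) = S₀ · [ (1 − f) · exp(−b · gᵀ D g) + f · exp(−b · D*) ]

with perfusion fraction *f* and pseudo-diffusion coefficient *D\**.
Correcting DTI for perfusion classically needs many low-b acquisitions —
expensive scan time for patients. Two estimation strategies are compared
throughout this package:

1. **Full fit (IVIM-corrected DTI)** — three stages:
   (A) a biexponential IVIM fit to the direction- and mask-averaged
   signal yields a shared D*; (B) a voxel-wise biexponential fit with D*
   fixed yields per-voxel (S₀, f, D); (C) the perfusion component
   S₀·f·exp(−b·D*) is subtracted and a 7-parameter nonlinear tensor fit
   is applied to the corrected signal over all b-values.
2. **High-b DTI** — discard every measurement with b < 200 s/mm², where
   the perfusion signal has decayed to negligibility, and fit the tensor
   directly: inherently IVIM-corrected, no f estimate, and much faster to
   acquire.

The scientific question the package operationalises: does the accelerated
high-b fit preserve the *sensitivity to injury* — the per-subject
difference Δ(injured − healthy) of the ROI-averaged parameters — that the
full fit provides? Agreement is quantified by ordinary least squares of
one method on the other (slope and R², banded as excellent/good/
moderate/poor) and by paired Wilcoxon signed-rank tests of the Δ values.

Because no patient data are distributed, a first-class synthetic-data
module generates studies with the published group structure: injured
muscle with eigenvalues (2.19, 1.73, 1.48)×10⁻³ mm²/s, contralateral
healthy muscle (2.03, 1.56, 1.34)×10⁻³ mm²/s, perfusion fraction
0.06 ± 0.02 in both tissues, a 55-measurement multi-shell acquisition
(8 × b=0; shells at 5–600 s/mm²; 32 directions at b ≥ 200), Rician noise
at a target b=0 SNR, and stored ground truth for every voxel.

## Worked example

```python
import ivimdti as m
from ivimdti.roi import roi_means, delta_sensitivity

study = m.build_phantom(m.PhantomSpec(snr=45.0, seed=7))
full = m.pipeline_full(study)
highb = m.pipeline_highb(study)
print(f"estimated SNR at b=0: {full.snr:.1f} (excluded: {full.excluded})")
for result in (full, highb):
    inj = roi_means(result, study.masks["injured"])
    heal = roi_means(result, study.masks["healthy"])
    delta = delta_sensitivity(inj, heal)
    line = ", ".join(f"{k}={v:.3f}" for k, v in inj.values.items())
    print(f"{result.method:>7} injured: {line}")
    print(f"{result.method:>7} delta(injured-healthy): "
          + ", ".join(f"{k}={v:+.3f}" for k, v in delta.deltas.items()))
```

prints

```
estimated SNR at b=0: 45.3 (excluded: False)
   full injured: md=1.793, fa=0.202, l1=2.184, l2=1.733, l3=1.462, f=0.061
   full delta(injured-healthy): md=+0.150, fa=-0.015, l1=+0.148, l2=+0.169, l3=+0.134, f=+0.001
 high_b injured: md=1.795, fa=0.202, l1=2.186, l2=1.734, l3=1.464
 high_b delta(injured-healthy): md=+0.151, fa=-0.015, l1=+0.149, l2=+0.168, l3=+0.135
```

Diffusivities are reported in 10⁻³ mm²/s. The injured ROI means recover
the generating values (MD 1.80, FA 0.20, f 0.06) at the simulated SNR of
45; the two methods give nearly identical maps and identical sensitivity
Δ, while only the full fit returns a perfusion fraction. The study-level
SNR estimate doubles as quality control: studies with SNR < 20 are
flagged for exclusion.

The same chain is available from the shell:

```sh
ivimdti simulate --seed 7 --snr 45 --subjects 1 --out work/sim
ivimdti fit --method both --dwi work/sim/subject_000/dwi.nii.gz \
    --bval work/sim/subject_000/dwi.bval --bvec work/sim/subject_000/dwi.bvec \
    --mask injured work/sim/subject_000/mask_injured.nii.gz \
    --mask healthy work/sim/subject_000/mask_healthy.nii.gz --out work/maps
ivimdti roi --maps full work/maps/full --maps high_b work/maps/high_b \
    --mask-injured work/sim/subject_000/mask_injured.nii.gz \
    --mask-healthy work/sim/subject_000/mask_healthy.nii.gz --out work/roi.csv
ivimdti compare --table work/roi.csv --out work/cmp
```

and `ivimdti run --seed 0 --subjects 16 --snr 45 --out work/exp` executes
the full cohort experiment (simulate → fit both methods → ROI table →
agreement regression → paired Δ tests) in one command.

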