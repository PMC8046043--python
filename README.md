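# dkipipe

Diffusion kurtosis imaging (DKI) analysis of segregated thalamic regions,
built to discriminate subcortical ischemic vascular disease (SIVD),
Alzheimer's disease (AD) and normal cognition (NC).

The thalamus is a relay hub whose microstructure is damaged differently by
vascular and neurodegenerative disease, and kurtosis metrics are more
sensitive than conventional tensor metrics to those gray-matter changes.
This package implements the full analysis chain as a tested, reusable
library: two-shell DKI model fitting, scalar metric maps, ROI aggregation
over a segregated thalamus atlas, deterministic thalamo-frontal
tractography, covariate-adjusted group statistics, and canonical
discriminant classification with bootstrap validation.  A synthetic-data
module generates every input the pipeline needs — acquisition schemes, DWI
signals from known tensors, fiber phantoms, and group-structured cohorts —
so the whole chain runs end-to-end with known ground truth.

## The model

For a gradient direction **n** and diffusion weighting *b* (s/mm²), the
kurtosis signal representation is

    S(b, n) = S0 · exp( −b·D_app(n) + (1/6)·b²·D_app(n)²·K_app(n) )

with the apparent diffusivity and kurtosis

    D_app(n) = Σᵢⱼ nᵢnⱼ Dᵢⱼ
    K_app(n) = (MD² / D_app(n)²) · Σᵢⱼₖₗ nᵢnⱼnₖnₗ Wᵢⱼₖₗ

where **D** is the rank-2 diffusion tensor (6 unique components), **W** the
fully symmetric rank-4 kurtosis tensor (15 unique components) and
MD = tr(D)/3.  The exponent is linear in D and in V = MD²·W, so fitting
proceeds by ordinary then weighted linear least squares on log-signals,
refined with Levenberg–Marquardt in the signal domain.  The seven scalar
metrics are MD, D_axial = λ₁, D_radial = (λ₂+λ₃)/2 and FA from the
eigensystem of D, plus MK (apparent kurtosis averaged over the acquisition's
gradient directions), K_axial (along the principal eigenvector e₁) and
K_radial (averaged in the plane perpendicular to e₁).

Classification uses canonical discriminant analysis: the generalized
eigenproblem of between-group vs pooled within-group scatter yields
canonical functions with eigenvalues λᵢ, canonical correlations
√(λᵢ/(1+λᵢ)) and Wilks' Λ = Π 1/(1+λᵢ); subjects are assigned to the
nearest group centroid in canonical space under equal priors, and accuracy
is validated by stratified bootstrap with a bias-corrected and accelerated
(BCa) interval.

## Worked example

```python
import numpy as np
from dkipipe import *

# fit one voxel of the two-shell protocol (30 directions, b = 1000/2000, 5 b0)
scheme = make_scheme(30, [1000, 2000], 5, seed=0)
truth = random_truth(np.random.default_rng(0))
signals = simulate_dwi(truth, scheme, snr=None)
fit = fit_voxel(signals, scheme)
m = dki_metrics(fit, scheme)
print(f"MD = {m.md*1e3:.3f} x10-3 mm2/s, FA = {m.fa:.3f}")
print(f"MK = {m.mk:.3f}, K_axial = {m.k_axial:.3f}, K_radial = {m.k_radial:.3f}")

# classify a synthetic 23/30/24 SIVD-AD-NC cohort from all segregated DKI metrics
table = simulate_cohort(default_cohort_spec(seed=0))
cols = feature_columns(["mk", "k_radial", "k_axial"], "segregated")
model = fit_cda(table[cols].to_numpy(), table["group"].to_numpy())
_, report = classify(model, table[cols].to_numpy(), table["group"].to_numpy())
print(f"Wilks' Lambda: {model.wilks_lambda.round(3)}")
print(f"canonical correlations: {model.canonical_correlations.round(3)}")
print(f"resubstitution accuracy: {report.accuracy:.1f}%")
```

Output:

```
MD = 0.837 x10-3 mm2/s, FA = 0.546
MK = 0.952, K_axial = 1.203, K_radial = 0.779
Wilks' Lambda: [0.019 0.374]
canonical correlations: [0.974 0.791]
resubstitution accuracy: 97.4%
```

The voxel metrics are the noiseless round-trip of a random ground-truth
tensor (recovered to machine precision).  The discriminant block reports the
two canonical functions separating the three groups: Λ near zero for the
span of both functions means almost all discriminant-score variance is
explained by group differences, and 97.4% of the 77 synthetic subjects are
assigned to their own group's centroid.

A thin CLI mirrors the main stages: `dki fit` (voxelwise maps from
NIfTI + bval/bvec), `dki track` (two-ROI connectivity), `dki cda`
(discriminant report) and `dki simulate` (synthetic cohort CSV).

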