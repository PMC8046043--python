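# Methods

This note records the scientific conventions, defaults and design choices
behind `dkipipe`, in the spirit of a model-description appendix.

## Signal model and tensor conventions

The kurtosis representation of the diffusion-weighted signal is

    ln S(b, n) = ln S0 − b·D_app(n) + (b²/6)·D_app(n)²·K_app(n)

with D_app(n) = nᵀDn and K_app(n) = (MD²/D_app²)·Σ nᵢnⱼnₖnₗWᵢⱼₖₗ.  W is
stored as the 15 unique components of a fully symmetric rank-4 tensor, in a
fixed monomial ordering (x⁴, y⁴, z⁴, x³y, …, xyz²) with multiplicities
(1, 1, 1, 4, …, 12).  Since D_app²·K_app = MD²·W_app, the exponent is linear
in (ln S0, D, V) where V = MD²·W, which is what both the linear stages and
the simulator exploit; W is recovered from a fit as V/MD².

Diffusivities are carried internally in mm²/s (brain values ≈ 1e-3) and
scaled to the conventional 10⁻³ mm²/s only at file boundaries (metric maps,
cohort tables).

Ground-truth kurtosis tensors are parameterised by the apparent kurtosis
along the three diffusion eigenvectors: in the eigenframe the tensor carries
W'ᵢᵢᵢᵢ = Kᵢλᵢ²/MD² plus cross terms W'ᵢᵢⱼⱼ = √(W'ᵢᵢᵢᵢW'ⱼⱼⱼⱼ)/3, a
construction that reduces exactly to the isotropic tensor when all three
axes agree.  A full 15-component W is also accepted.

## Acquisition scheme

The default protocol is the clinical two-shell scheme: 30 gradient
directions at b = 1,000 and 2,000 s/mm² plus five b0 volumes (65 volumes).
Because the vendor's gradient table is not published, directions are laid
out by electrostatic repulsion on the hemisphere (antipodally symmetric
Coulomb energy, projected gradient descent, seeded and reproducible).  The
design matrix of the 65-volume scheme has full column rank 22
(intercept + 6 + 15).

## Fitting

1. OLS on log-signals initialises the 22 linear parameters.
2. WLS with weights equal to the squared predicted signals corrects the
   heteroscedasticity introduced by the log transform.
3. Levenberg–Marquardt (scipy `least_squares`, `method="lm"`) minimises
   squared error in the signal domain, relative-step tolerance 1e-8, at most
   500 function evaluations; non-convergence returns the best iterate
   flagged `converged=False`.

After fitting, D is projected to positive semi-definite by clipping negative
eigenvalues at zero, and directional apparent kurtosis entering the scalar
metrics is clipped to the plausibility range [0, 3].  Voxels with
non-positive signals are skipped and left masked, never imputed.

## Scalar metrics

MK is the arithmetic mean of K_app over the acquisition's 30 gradient
directions — the acquisition convention rather than the analytic spherical
mean; on random anisotropic tensors the two differ by well under 0.01
(checked against a 10,000-direction spherical average).  K_axial is K_app
along e₁.  K_radial averages 64 equally spaced directions in the plane
perpendicular to e₁, which converges to the perpendicular-plane average.
MD/FA from the kurtosis fit agree with a pure tensor fit on b = 1,000 data
only up to the Gaussian-model approximation error; this is a property of the
models, not asserted numerically.

## Noise model

Magnitude MRI noise is Rician: independent Gaussian noise of standard
deviation σ on the real and imaginary channels followed by the magnitude,
with σ = S0_ref/SNR defined against the mean ground-truth b0 signal.  The
clinical acquisition's SNR is unreported; tests use SNR 50, where the median
MK bias over 500 repeats is below 0.02.  A Gaussian option exists for
debugging.

## Synthetic cohorts

The default cohort reproduces the study conditions: group sizes 23 (SIVD) /
30 (AD) / 24 (NC), whole-thalamus metric means/SDs per group and hemisphere
from the published group table, and demographic/cognition distributions
(age, education, Fazekas ratings, CDR-SOB, MMSE, CASI) from the published
demographics.  Subregion-level statistics are not published numerically, so
subregion means are derived from the hemisphere mean via fixed
multiplicative offsets (−5% … +5% across PUL, ANT, MedioD, VLD, C, VA, VLV)
with the hemisphere SD; every subregion therefore inherits the
hemisphere-level group contrasts, which is what makes the segregated
feature sets at least as discriminative as the whole-thalamus ones — a
built-in property of the generator, not a claim about clinical data.

Selected metric–cognition pairs are linked through a Gaussian copula at the
published pooled partial-correlation values (treated as plain correlations
at generation time; covariates are simulated independently).  Infeasible
(non-positive-definite) link structures are rejected with the implicated
pair named.  After sampling, FA is clipped to [0, 1] and kurtosis metrics to
[0, 3]; Fazekas and cognition columns are left continuous and unclipped
(ordinal rounding would perturb the copula correlations more than it adds
realism).

What the generator does *not* emulate: spatial correlation between ROIs
within a subject, registration error, partial-volume mixing, head motion and
eddy currents, and floor/ceiling effects in cognitive instruments.  Passing
tests therefore demonstrate correctness of the estimators and the pipeline
plumbing under the published group-level distributions, not robustness to
those real-data artifacts.

## ROI aggregation

All volumes are processed in a shared voxel grid (spatial normalisation is
upstream of this package).  ROI means exclude ventricle-mask voxels; fully
masked ROIs are reported with a zero count rather than dropped.  The
whole-thalamus value is (left + right)/2 where each hemisphere mean is
voxel-weighted over that hemisphere's subregion voxels; a
mean-of-subregion-means option exists.  For synthetic data a simple
b0-intensity-quantile ventricle mask generator is provided (CSF is bright at
b = 0).

## Tractography

Deterministic Euler tracking at 1 mm steps, FA threshold 0.2, angular
threshold 30°, length gate 30–300 mm.  Seeds are uniform over
suprathreshold voxels with sub-voxel jitter; each seed propagates in both
directions.  The per-streamline smoothing fraction w is drawn once per
streamline, uniformly in [0, 0.95], and the propagation direction is
(1−w)·local + w·previous, renormalised — drawing once per streamline (not
per step) matches the behaviour of fixing a smoothing percentage for a
propagation.  The local eigenvector is sign-aligned with the incoming
direction before blending.  The stopping rule compares the *raw* local
direction with the previous propagation direction, so heavy smoothing can
never drag a streamline across an interface that violates the angular
threshold (a 90° crossing is structurally impossible).  FA is interpolated
trilinearly; directions use nearest-neighbour lookup to avoid
eigenvector-interpolation sign artifacts.  The default seed count is a
desk-scale 50,000; the protocol's 3,000,000 is a parameter choice.
Connectivity between two ROIs counts streamlines with at least one point in
each; tract-averaged FA/MK are means over retained streamlines of
per-streamline nearest-voxel point means.

## Group statistics

* **QC**: |Z| > 2 against the sample mean/SD flags outliers;
  quantile–quantile points are exported for visual inspection, not used as
  an automated gate.
* **ANCOVA**: linear model with sum-to-zero group contrasts; group F from
  type-III sums of squares (the convention of the statistics package used
  in the original analysis); partial η² = SS_group/(SS_group+SS_error).
  Pairwise contrasts compare covariate-adjusted means with
  Bonferroni-adjusted p (capped at 1) and Bonferroni-adjusted 95% CIs.
  Named covariate tiers: `age_edu` and `age_edu_fazekas` (all three Fazekas
  components; entering the total only is a caller choice).
* **FDR**: Benjamini–Hochberg step-up; the family is configurable, default
  all ROIs of one metric.
* **Partial correlation**: Pearson correlation of OLS residuals, p from t
  with n − k − 2 df.
* **Mahalanobis filter**: squared distance from the predictor centroid per
  degree of freedom > 2 removes a row; the mirrored "< −2" branch of the
  stated rule is vacuous for a non-negative distance and omitted.  Singular
  covariances are ridge-regularised with a warning.
* **Stepwise regression**: forward entry at p ≤ 0.05, backward removal at
  p ≥ 0.10 on the partial F (standard defaults); standardised β, t and p
  are reported per retained predictor; an empty selection is a valid
  outcome ("no best predictor").

## Discriminant analysis

Between-group scatter B vs pooled within-group scatter S_w solved as a
symmetric-definite generalized eigenproblem; K = min(groups−1, features)
functions ordered by decreasing eigenvalue; coefficients scaled so canonical
scores have pooled within-group variance 1.  Wilks' Λ(k..K) = Π_{i≥k}
1/(1+λᵢ) with Bartlett's χ² approximation for significance; canonical
correlation √(λ/(1+λ)).  Classification is nearest-centroid in canonical
space under equal priors, and the reported accuracy is resubstitution, the
convention of the classical statistics output being mirrored; with 42
segregated features on 77 subjects this is optimistic by construction,
which is one reason the synthetic pipeline reaches ~99–100% where the
clinical analysis reported 97.4%.  A ridge term (fraction of trace) is
available for singular within-group scatter and is off by default.

Bootstrap validation resamples subjects with replacement within groups,
refits and records resubstitution accuracy; the validated accuracy is the
mean of the resample distribution and the interval is BCa (jackknife
acceleration).  Outlier removal before resampling applies the |Z| > 2 rule
to the canonical scores of an initial fit rather than to every feature
column: a per-feature union rule removes ≈ 1−0.954^p of subjects and
degenerates for wide feature sets (86% at p = 42), so it cannot be what a
42-feature validated analysis used; the score-based rule keeps the removal
rate feature-count-independent.  Per-feature removal remains available as
an option.

## Problem sizes and determinism

Default test and acceptance sizes: 100 voxels for noiseless recovery, 500
noise repeats for the MK bias, 10,000 directions for the dense spherical
oracle, 50,000 tractography seeds, 1,000 bootstrap resamples.  Every random
operation takes an explicit seed and is bit-reproducible; the acceptance
script derives all of its generator seeds from a single `--seed`.

## Known limitations

* The fit is unconstrained beyond PSD projection of D and [0, 3] clipping of
  directional kurtosis; fully constrained quadratic-programming estimation
  is not implemented.
* Single-tensor tractography cannot represent crossing fibers (the crossing
  phantom deliberately carries the dominant bundle's direction in the
  overlap).
* Kurtosis anisotropy, kurtosis FA and generalized FA are out of scope, as
  are denoising, registration and distortion correction.
* The cohort generator samples ROI columns independently within a subject
  (apart from the cognition links), so multivariate structure beyond group
  means/SDs is not calibrated to clinical data.
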