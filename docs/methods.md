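# Methods

## The model

Each subject contributes a feature vector of masked grey-matter voxel
probabilities followed by masked white-matter voxel probabilities (C order
over the mask; any fixed order is equivalent for a dot-product kernel, but the
order is pinned so vectors are byte-identical across runs). The similarity
kernel is the Gram matrix of these vectors, divided by the feature length
(`scale_mode="by_voxel_count"`, the default) so that kernel entries stay O(1)
regardless of grid size; `none` and `trace_normalized` modes are available.

Age is regressed on the kernel by Gaussian-process regression with constant
mean μ = mean(training ages) and covariance s·K + σ²I. For fixed (s, σ²) the
predictive mean equals kernel ridge regression — the closed form used as the
test-suite oracle. When hyperparameters are optimized, the Gaussian log
marginal likelihood is maximized over (log s, log σ²) by L-BFGS-B from three
fixed starts; because K is fixed, C = sK + σ²I shares K's eigenvectors, so
each likelihood evaluation costs O(n) after one eigendecomposition. One start
uses a deliberately large signal scale because the flat "all noise"
solution (s→0, σ² = var(y)) is a genuine local optimum of the likelihood.

**Kernel centering.** Tissue maps share a large common component (the average
anatomy). In dot-product space this component dominates every kernel entry and
its cross-terms with voxel noise can bury the age signal; on synthetic cohorts
the uncentered marginal likelihood prefers the no-signal solution outright. The
model therefore double-centers the training Gram matrix by default —
algebraically identical to subtracting the mean training image from every
feature vector — and applies the matching correction to test-vs-training cross
kernels using stored training column means. `center=False` recovers the
textbook uncentered model (used by the closed-form oracle tests, where e.g. a
zero cross-kernel row must revert to the prior mean μ).

Cross-validation uses a seeded uniform random partition into near-equal folds
(sizes differ by at most 1); any hyperparameter optimization happens inside
the training folds only. With fewer subjects than folds the fold count is
reduced with a warning. The permutation test permutes age labels, repeats the
full cross-validation with the same fold assignment, and reports the
one-sided upper-tail p of the observed CV correlation with +1 smoothing,
p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm). brain-PAD is exactly
predicted age − chronological age, in years.

## Statistics

Two-group comparisons use the pooled-variance (Student) t-test: the published
effect ± SEM and t values are reproduced exactly by the pooled formula from
the printed (n, mean, SD) triples, which is how the variant was identified.
`t_test_from_summary` and `t_test_pooled` share one implementation, so the
summary and raw routes agree to machine precision. The chi-squared test is
Pearson's without continuity correction (this matches the published sex-ratio
p ≈ 0.70; Yates' correction is available behind a flag). Mann-Whitney U uses
exact enumeration for small untied samples and the tie-corrected normal
approximation otherwise. Covariate adjustment is OLS of brain-PAD on an
intercept, a patient-group indicator, and raw-scale covariates (the published
volume coefficients are on the raw scale, so no standardization is applied);
interaction tests add the group × covariate product. BMI matching keeps
patients with BMI ≤ max(control BMI) and controls with BMI ≥ min(patient BMI);
boundary subjects are retained (≤/≥), the convention implied by the published
retained ranges even though the prose prints strict inequalities. No
multiple-testing correction is applied anywhere, matching the original
analysis. Single-subject comparison reports z = (pad − mean(norms))/sd(norms)
and the empirical percentile.

The cohort-2 normative brain-PAD SD is printed as 6.48 in the results and 6.52
in the abstract of the source study; the fixture stores both and computations
use 6.48. The cohort-1 age-comparison p appears as 0.74 (table) and 0.73
(text); the table value is stored with the discrepancy noted. Published tissue
volumes are labelled cm³ but are litre-scale numbers; this package computes
volumes in ml (Σ probability × voxel volume / 1000) and documents the reading
rather than guessing the table's intent.

## Synthetic data generator

Tissue maps are generated on a configurable grid (default 24×28×24 voxels at
4 mm; the repeated-seed experiments use 12×14×12 at 8 mm) as

    gm = clip(gm_baseline − gm_slope · effective_age + ε, 0, 1),   ε ~ N(0, noise_sd²) i.i.d.
    wm analogous;   csf = clip(1 − gm − wm, 0, 1);   optional Gaussian smoothing.

Baselines are smooth head-phantom fields (a cortical GM shell peaking at 0.75,
a WM core peaking at 0.70) and slopes are proportional to baseline at 0.4%/yr
— within the range of reported adult GM/WM volume decline — so probabilities
stay in [0, 1] across the valid age range (0–90 y). `noise_sd = 0.05` was
chosen as a plausible inter-subject variability for smoothed tissue maps.
The group aging offset Δ enters only the *effective* age used for tissue
generation, never the recorded chronological age. Demographics (uniform ages,
Bernoulli sex, BMI/IQ from normals truncated to the published ranges) and maps
draw from per-subject substreams keyed by (stream, group index, subject
index) under one master seed, so enlarging a cohort never reshuffles existing
subjects.

What the generator does **not** emulate: biological heterogeneity in brain
aging (every simulated subject of the same effective age has the same expected
anatomy), scanner/site effects, registration error, and spatially correlated
anatomical variability. Consequently the synthetic age-prediction error is
sub-year — far below the several-year MAE of real brain-age models — so
passing tests demonstrate correctness of the machinery and recoverability of a
known offset, not real-world accuracy. The published training-set accuracy
(r = 0.94, MAE 5.01 y on n = 2001 real scans) cannot be reproduced without
those scans and is treated as context, not a target.

## Validation experiments and their problem sizes

- **Offset recovery**: train on n=300 (ages 19–56, Δ=0), score n=20 patients
  (Δ=7) vs n=40 controls (ages 19–29), 50 seeds on the reduced grid. The mean
  estimated group difference is ≈ 6.8 y. The ~3% attenuation is regression
  dilution: kernel regression on noisy features shrinks predictions toward
  the training mean (prediction-vs-effective-age slope ≈ 0.965 here), biasing
  the group difference by (1−slope)·Δ ≈ 0.24 y. With sub-year prediction
  noise the pooled-t 95% CIs are ≈ ±0.55 y wide, so their coverage of the
  true Δ runs slightly below nominal (≈ 88% over 50 seeds). The optional
  `AgeBiasCorrection` (a linear recalibration of predictions against training
  age, fit on out-of-fold training predictions) removes the attenuation
  (mean ≈ 7.0, coverage ≥ 90%) but is **off by default** because the original
  analysis applies no such correction — enabling it changes the estimand.
- **Null calibration**: with pure-noise features, the permutation test
  (n_perm=99, 200 repeats, fixed hyperparameters for speed — permutation
  validity requires only exchangeability) rejects at α=0.05 at the nominal
  rate within the exact binomial band; pooled-t CIs cover a zero group effect
  at ≈ 95% over 500 simulations.
- **Oracle equivalence**: GPR predictive means match the closed-form kernel
  ridge solution to 1e-8 on 20 random instances (n ≤ 30); Gram matrices match
  a brute-force double loop to 1e-10.

These sizes keep the full suite and the acceptance script to a few minutes on
one CPU while leaving Monte-Carlo error well inside the asserted bands.

## Numerical and design choices

- Smoothing: separable Gaussian, σ_axis = FWHM / (2√(2 ln 2)) / voxel_mm_axis,
  nearest-edge boundary replication; FWHM 0 is the identity. The volume
  integral is conserved to 1e-8 (relative) on zero-padded volumes.
- Mask: voxels with cohort-mean GM+WM > 0.05 (threshold configurable); the
  training mask is reused verbatim for test cohorts, and a mask-identity hash
  guards against mixing features from different masks.
- Cholesky factorization with a single 1e-8·trace/n jitter retry (logged) for
  near-singular covariances; kernels are validated symmetric and PSD up to
  −1e-8·trace/n before fitting.
- Degenerate inputs: constant ages yield constant predictions; an all-zero
  mask yields a length-0 feature vector with a warning; zero pooled variance,
  zero margins, zero normative SD and rank-deficient designs raise errors
  naming the offending input.
- Pipeline: stages are keyed by content hashes of configuration plus inputs;
  unchanged stages are skipped, and the manifest records the master seed and
  output hashes so reports are reproducible byte-for-byte (no timestamps).
  In the synthetic world ICV is nearly constant by construction (CSF closes
  the tissue budget), so ICV-adjusted effects carry very wide CIs there.

## Known limitations

- The estimator inherits the brain-age field's regression-to-the-mean bias;
  see the recovery experiment above. Group contrasts at matched chronological
  ages are mildly attenuated, never inflated in sign.
- Tissue volumes assume probability-valued inputs; quantitative maps outside
  [0, 1] are rejected rather than rescaled.
- The CLI covers the simulate-to-report path only; applying a trained model to
  externally supplied NIfTI cohorts is done through the Python API
  (`read_volume` → `vectorize_concat` → `build_cross_kernel` → `predict_gpr`).
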