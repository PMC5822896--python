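# Methods

## The problem

Regional glucose metabolism measured by FDG-PET declines with normal aging in
frontal, cingulate, insular and superior temporal cortex — the same territory
where Alzheimer's disease produces hypometabolism. A radiologist reading an
SUVR image therefore sees age and disease superimposed. `petage` implements a
data-driven procedure that (a) locates the brain regions whose signal declines
linearly with age in a healthy cohort, (b) fits the decline rate, and (c)
removes the age-attributable part of the signal from new scans so that what
remains is more attributable to disease.

All images are assumed co-registered to one voxel grid (spatial normalisation
is upstream of this package), so no affine/world-coordinate math is performed.

## Pipeline

1. **Spatial ICA screening** (`decomposition`). The subject x voxel stack is
   demeaned per voxel and decomposed by fixed-point negentropy-maximising ICA
   (FastICA, logcosh contrast, tol 1e-6, max 500 iterations, up to 3 seed
   restarts on non-convergence, non-convergence flagged in the result). Spatial
   maps are the independent sources; per-subject loadings are the mixing
   weights. Scale convention: maps have unit L2 norm and positive skewness,
   loading columns unit variance, and a per-component scale vector carries the
   reconstruction magnitude (`stack ~ voxel_mean + subject_offset +
   loadings @ diag(scales) @ maps`). Without the explicit scale vector the two
   unit conventions would destroy reconstructability.

   Each component's loading is regressed on age with linear and quadratic
   least squares; R² and an overall F-test p-value are reported for both. A
   component is *monotone* when the quadratic vertex falls outside the
   observed age range — the operationalisation of "the linear and quadratic
   fitted curves coincide". `select_aging_component` returns the monotone,
   negatively trending component with maximal R² among those with p < alpha
   (default 0.05), ties to the lower index. Component sign is made canonical
   by map skewness; the age-direction flip (map and loading together) is
   exposed as `ComponentSet.oriented`.

   The number of components defaults to the smallest PCA order retaining 90 %
   of variance (capped at n_subjects − 1); pipeline configs set it explicitly.

2. **Integer voxel-value map**. The upstream multimodal-ICA toolkit that
   inspired this stage attaches an integer "voxel value" (1..38) to each
   component voxel; its exact computation is not published, so the package
   uses a documented stand-in: voxels whose map deviation from the map median
   exceeds 2.5 robust standard deviations (1.4826 x MAD) form the support, and
   surviving magnitudes are discretized monotonically to `ceil(v_max * s /
   s_max)`. Median-centering matters: after per-component centering, the
   inactive majority of a map sits at a small nonzero constant, not at zero.

3. **Sigma sweep** (`sweep`). For every integer threshold sigma in 1..v_max a
   nested ROI mask (`voxel value >= sigma`) is formed and each subject's SUVR
   mean — mean ROI intensity over mean reference-region intensity — is
   computed against the paracentral-lobule analogue (regions 69/70 by
   default; cerebellar and whole-brain references are supported through
   configuration). The SUVR–age Pearson correlation, its t-transform p-value
   (n − 2 df) and the OLS slope are estimated over repeated random subsamples
   (default 250 of n subjects, 3000 replicates) and summarised as mean ± SD
   over replicates (the dispersion convention is SD; the sources describing
   this design report "±" columns without naming the dispersion). One set of
   subsample draws is shared by all sigmas so thresholds are compared on
   identical replicates — this also makes identical masks yield identical
   records. `sigma_star` maximises |mean r|, ties to the smallest sigma
   (favouring the larger, more stable ROI). Masks with fewer than
   `min_voxels` (default 10) voxels are skipped with a warning; the floor is
   deliberately low because very small masks (tens of voxels) are a regime
   the method must reach.

4. **Age model** (`agemodel`). `SUVR_mean = beta_C * age + p2` is fitted on
   the discovery cohort's SUVR means over the final mask; beta_C is the mean
   subsampled OLS slope (same resampling convention as the sweep), the
   intercept p2 comes from the full-sample fit and is stored but plays no role
   in the correction. The correction subtracts the age-attributable offset:
   `Index_cor = Index_tar − beta_C * age`. With `n_draw = n` and
   `n_rep = 1` the estimator collapses to full-sample OLS and the corrected
   index is exactly orthogonal to age. A voxel-level variant fits one slope
   per voxel inside the final mask and corrects voxelwise, leaving voxels
   outside the mask untouched. New cohorts are corrected with the
   discovery-cohort beta_C by default (transfer setting); a per-cohort refit
   is available behind a flag since either protocol is defensible.

5. **Evaluation** (`evaluate`). Before/after comparisons on an independent
   healthy + disease cohort: Pearson SUVR–age correlation in the healthy
   group; partial correlations of SUVR with MMSE, CDRSB and meta-ROI FDG in
   the disease group controlling education, sex (coded 0/1) and ApoE4 allele
   count (partial correlation by OLS residualization with intercept —
   numerically identical to the inverse-correlation-matrix formulation but
   auditable — with p from the t transform at n − k − 2 df); Welch's t-test
   between groups (pooled-variance mode behind a flag); and leave-one-out
   PCA + linear-SVM classification, PCA refit on the training folds of every
   split (retaining 95 % variance by default), AUC computed from SVM decision
   values. Age bins thinner than 5 subjects can be merged into their nearest
   neighbour (`merge_thin_bins`).

## Synthetic cohorts

The generator (`synthetic`) emulates exactly the statistical structure the
analysis assumes, not PET physics. Defaults are the discovery-study
conditions:

| parameter | default | meaning |
|---|---|---|
| n_subjects | 255 | healthy discovery cohort size |
| age_range | 20–80 y | uniform sampling (a decade-quota mode mirrors the real cohort's age table) |
| grid | 32 x 40 x 32 @ 4 mm | desk-scale analogue of the 91 x 109 x 91 @ 2 mm MNI grid |
| baseline | 1.0 | brain intensity at age 0, arbitrary units |
| decline_per_year | −0.004 | linear decline in the 9 aging parcels |
| noise_sd | 0.05 | i.i.d. Gaussian voxel noise (optionally smoothed for spatial correlation) |
| regional_noise_sd | 0.0 | per-subject, per-region biological offsets |
| global_scale_sd | 0.0 | per-subject multiplicative global factor |
| ad_fraction / ad_deficit | 0.0 / 0.08 | disease group share; extra hypometabolism, scaled by a per-subject severity ~ N(1, 0.25) |

The block atlas names its parcels after the anatomy they stand in for
(inferior orbital frontal, medial frontal, insula, cingulate, superior
temporal poles as the aging set; paracentral lobule as the reference;
cerebellar parcels as alternative reference candidates). Reference regions are
age-flat *and* excluded from the regional-variability term: metabolic
stability is precisely why a region is chosen as an SUVR denominator.
Clinical scores are linear in the disease severity with Gaussian noise,
calibrated so group marginals echo typical values (MMSE 29.0 vs 23.2, CDRSB
0.0 vs 4.1, meta-ROI FDG 1.3 vs 1.1); this is a calibration, not ground
truth. Evaluation-cohort configurations additionally use
`regional_noise_sd = 0.03` and `global_scale_sd = 0.05`: with i.i.d. voxel
noise alone, averaging over thousands of mask voxels drives the SUVR–age
correlation to ~1, which no real cohort shows.

A sweep phantom (`make_sweep_phantom`) plants the age signal only in voxels
whose integer value is at least a chosen sigma_true; its value histogram
follows an exponential-decay-plus-floor profile (low values dominate, the top
values keep a tail of ~10 voxels) and its noise condition is 0.40 so that the
population r(sigma) curve has an identifiable peak at sigma_true — verified
with a closed-form correlation oracle when the profile was designed.

**What passing tests do and do not show.** The synthetic cohorts have
rectangular parcels, Gaussian noise, a single linear age effect and
conditionally independent clinical noise. Passing tests show the estimators
recover what was planted and that the correction behaves directionally as
intended under those assumptions; they say nothing about registration error,
partial-volume effects, non-linear aging, scanner batch effects, or cohort
selection bias in real data.

## Numerical choices and caveats

* Smoothing uses reflect (mirror) boundaries; sigma = FWHM / (2 sqrt(2 ln 2))
  per axis in voxel units.
* Missing tabular values are empty TSV fields; operations needing a covariate
  drop incomplete rows loudly (count reported) rather than imputing.
* NIfTI is written single-file `.nii/.nii.gz`, float32.
* Resampling replicates with zero variance are skipped with a warning and
  counted; a fully degenerate input errors.
* Two zero-variance groups with equal means return t = 0, p = 1 by
  convention in the t-test.
* **Selection bias in beta_C.** When the ROI is chosen from the same noisy
  data (high-|map| voxels of an age-correlated component), the fitted |beta_C|
  is inflated by a winner's-curse effect (~5–10 % at demo scale): selected
  voxels have noise aligned with the age-correlated loading. This is intrinsic
  to the data-driven ROI selection procedure, not an implementation artifact;
  slope-recovery tests therefore fit on the generator-truth mask, while the
  pipeline reports the honestly selected-mask estimate.
* The documentation example rate −0.00415 per year is the canonical decline
  slope used in worked examples; an alternative printed value (−0.00539)
  circulating for the same quantity is inconsistent with the model equation it
  accompanies and is treated as an erratum.
* Nonlinear (quadratic) age-correction models are out of scope by design;
  quadratic fits are used only for screening and monotonicity assessment.

## Problem sizes used by tests and the acceptance script

Statistical tests run at the discovery scale (255 subjects, 32 x 40 x 32
grid, 3000 resampling replicates). The evaluation battery uses 150-subject
transfer cohorts (100 HC / 50 AD) for direction checks, 30 + 30 subjects per
LOOCV classification in tests, and a 262 HC + 50 AD cohort with 50 + 50
age-matched classification in the acceptance script. ICA fixtures use a
12 x 15 x 12 grid with 60 subjects and three planted sparse sources. The
end-to-end demo runs 60-subject cohorts with 300 resampling replicates.
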