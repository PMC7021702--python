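# Methods

## The analysis

`favoxel` tests whether voxel-wise FA patterns discriminate subject groups
(AD, amnestic MCI, healthy controls), and where. For one binary contrast
the pipeline is: mask the per-subject FA maps to an ROI (or the atlas
union, "whole brain"), rank voxels by the two-class Fisher score computed
on *training subjects only*, keep voxels strictly above a threshold —
optionally only those whose training class means show an FA decrease in
the patient group — train a linear SVM (C = 1) on the kept voxels, and
score the held-out subjects. The procedure is repeated over a
Fisher-threshold grid (default 0 to 2 in steps of 0.1) to produce an
accuracy curve, and a descriptive Fisher map on all subjects localizes
the supra-threshold voxels.

### Fisher score

Fⱼ = (μ₁ⱼ − μ₂ⱼ)² / (s²₁ⱼ + s²₂ⱼ) per voxel j, with unbiased (n−1)
variances. This is the standard two-class univariate criterion; other
variants could be slotted in behind `fisher_score`. Degenerate voxels:
both class variances zero with differing means scores +inf (always
selected); identical constant values score 0. Selection uses a strict
inequality (F > t), so threshold 0 already drops exactly-zero voxels.

### Cross-validation and leakage

Feature selection is nested inside every training fold; the held-out
subjects contribute nothing to scores, signs or the SVM (asserted by a
mutation test: corrupting a held-out row changes neither the fold's
selected voxel set nor its weight vector).

Fold structure: by default one subject of *each* class is held out per
fold — k folds for k subjects per class, 30 predictions for a 15-vs-15
contrast, accuracy granularity 1/30. The reason is statistical, not
cosmetic: with single-subject folds every training set is 14-vs-15, and
for weak signal a C = 1 linear SVM drifts toward the majority class,
which is always the class the held-out subject does *not* belong to.
Measured on null data this pushes leave-one-subject-out accuracy well
below 0.5 (to exactly 0 in the low-noise limit) — the familiar
below-chance bias of LOOCV on balanced data. Paired folds keep training
sets balanced and the null at 0.5. Single-subject folds remain available
(`loocv(..., leave_one_pair_out=False)`).

Empty selection in a fold (e.g. an increase-restricted rule when every
voxel decreases) leaves no feature basis; the fold's held-out subjects
receive the negative class of the ordered pair, the same convention as a
decision-function tie (f = 0). For balanced folds this scores at chance,
which is the behaviour the directional-asymmetry analysis expects from an
uninformative restriction.

### SVM determinism and ties

`SVC(kernel="linear", C=1, tol=1e-6)`; prediction is `f(x) > 0` for the
positive class, with exact zeros resolved to the negative class. No
feature scaling is applied — FA is already bounded in [0, 1].

### Threshold sweep caveat

The sweep's "best accuracy at threshold t*" selects t* by *test*
accuracy, so it is an optimistically biased summary of the curve; it is
reported as a descriptive operating point, never as an unbiased accuracy
estimate.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:
per-subject FA volumes on one shared 20×20×20 grid at 2.5 mm isotropic
(matching a typical DTI acquisition voxel), three groups of 15, and a
planted mean FA decrease at every voxel of one designated bilateral
region for AD (`effect_delta_ad`, default 0.10; `effect_delta_mci`
default 0, i.e. MCI is distributionally identical to controls). Each
subject volume is

baseline(v) − δ_group·1[v ∈ region] + Σ_r offset_r·1[v ∈ r] + jitter(v),

clipped to [0, 1], where

- **baseline**: 0.5 plus a smooth field (SD 0.03, FWHM 6 mm), shared by
  all subjects;
- **regional offsets**: one Gaussian scalar per atlas region per subject
  (SD `region_offset_sd` = 0.06, hemispheres pooled, background
  included), emulating tract-level between-subject variability;
- **jitter**: a per-subject smooth Gaussian field (SD `subject_sd` =
  0.04, FWHM `smoothness` = 6 mm), variance-renormalized after smoothing.

The regional-offset component is the load-bearing realism choice. With
voxel-level noise alone (smooth or not), averaging the ~480 region voxels
estimates the planted delta essentially noise-free, and classification
saturates at 100% for any usable delta — no real FA study behaves that
way. A spatially *global* per-subject offset does not help either: a
linear SVM cancels it exactly using out-of-region voxels as a reference.
Independent per-tract offsets bound the achievable accuracy by
δ / offset-SD regardless of region size and cannot be regressed out from
other regions, reproducing the regime actually reported for this kind of
analysis: whole-brain accuracy well below ceiling without selection,
improved by Fisher-threshold selection, with supra-threshold voxels
concentrated in the affected region. Defaults were fixed once from that
qualitative pattern.

What the generator does **not** model: anatomy (regions are mirrored
blocks), partial-volume and CSF-contamination effects, spatially varying
noise, registration error, scanner/site effects beyond the offset term,
or any MCI-specific pathology. Passing tests therefore demonstrate
correctness and calibration of the *procedure* under a plausible
covariance structure, not clinical performance.

All randomness derives from one integer seed; per-subject streams are
spawned from (seed, subject index), so cohorts are bit-reproducible and
subjects are independent.

Clipping to [0, 1] is a safety net only: under the default configuration
(total between-subject SD ≈ 0.078 around 0.5) the bound sits ≈ 5 SD away
and the tests assert no voxel is actually clipped.

### DWI-level path

For exercising the tensor stage, `make_tensor_phantom` builds axially
symmetric tensors whose analytic FA hits a per-region target exactly
(closed-form inversion of FA = (λ₁−λ₂)/√(λ₁²+2λ₂²) at fixed mean
diffusivity 0.7×10⁻³ mm²/s) with a smoothly rotating principal axis, and
`simulate_dwi` evaluates S = S₀ exp(−b gᵀDg) over a 1 b0 + 32-direction
scheme at b = 1000 s/mm² (Fibonacci-spiral directions), adding Rician
noise at finite SNR (two Gaussian channels of SD S₀/SNR, magnitude
taken). The tensor fit is ordinary log-linear least squares — exact on
noise-free data, which the round-trip tests exploit (max FA error ~1e-15
at infinite SNR; mean error < 0.03 at SNR 30). Negative eigenvalues are
clamped to zero before the FA formula; non-positive signals are floored
at 1e-10·S₀ and flag the voxel in a validity mask; the zero tensor gets
FA 0 by convention.

## ANOVA from summaries

Group-comparison tables report (n, mean, SD) per group; the one-way
ANOVA F is a closed-form function of those triples
(SS_between = Σnᵢ(meanᵢ−grand)²; SS_within = Σ(nᵢ−1)sdᵢ²), so the printed
p-value column is recomputable and auditable without raw data. SDs are
treated as sample (n−1) SDs; this convention affects the third decimal.
Equivalence with a raw-data ANOVA is tested by constructing samples that
realise the summaries exactly. A p printed as "0.000" is matched as
p < 0.0005. Zero within-group variance with distinct means yields p = 0
with a warning.

## Problem sizes and tolerances

Simulation-based checks use 20 cohorts (50 label permutations for the
null) at the 20³ grid — sizes chosen so the whole suite exercises every
stage at full cohort scale while remaining desk-runnable. Monte-Carlo
assertions use 3·SE bounds (binomial 99% bands for accuracies); exact
algebraic identities use 1e-10…1e-12; the SVM solver runs at tol = 1e-6.
Grids must match across subjects to 1e-4 mm in the affine; no resampling
is performed.

## Known limitations

- Real AAL/JHU-DTI atlases are not bundled; any label NIfTI + JSON name
  table in the same schema works. The derived
  `parahippocampal_cingulum` region (intersection of hippocampal cingulum
  and parahippocampal gyrus) is empty for single-label atlases like the
  toy one; it is meaningful only when overlapping masks from two atlases
  are merged into one name table.
- Unbalanced group sizes require `leave_one_pair_out=False`.
- The whole-brain mask is the union of atlas labels; no independent brain
  mask is supported.
- No eddy/motion/EPI correction or spatial normalization: inputs are
  assumed preprocessed into a common space.
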