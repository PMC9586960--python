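# Methods notes

This document records the models, conventions and design choices behind
`nigrascan`, in the spirit of a package reference manual: what is computed,
under which assumptions, and where the genuinely open choices were made.

## Signal model and T2\* fitting

Each voxel of the multi-echo gradient-echo acquisition is modelled as a
mono-exponential decay, S(TE) = S₀·exp(−TE/T2\*), sampled at three echo
times (defaults 7.91, 15.96, 24 ms). T2\* is estimated per voxel by
ordinary least squares of ln S on TE (closed form, exact on noiseless
data); a nonlinear least-squares fit agrees on noiseless input and the
log-linear form was chosen for speed and determinism. Voxels with any
nonpositive echo intensity or a non-decaying slope (slope ≥ −10⁻¹², the
tolerance absorbing float summation error on exactly flat signals) are
flagged invalid and excluded from all downstream statistics rather than
imputed. Valid estimates are clamped to (0, 150] ms: near-flat decays
otherwise produce arbitrarily large values that would dominate VOI means.

The neuromelanin-sensitive image is the first (shortest-TE) echo,
unchanged. It is normalized by its mean over a normal-appearing
white-matter reference mask disjoint from the rostral midbrain working
region; the phantom provides this mask directly and no tissue
classification is implemented.

## VOI definition

Templates are voxelwise means of control-subject (NMNC) images over the
union of their midbrain masks; all phantoms share one grid, so no
registration step exists (inter-subject alignment is assumed perfect).
A 1-D k-means with k = 3 partitions template voxels by intensity; labels
are re-ordered by ascending centroid so cluster identity is deterministic
and invariant to initialization relabelling. Cluster→tissue assignment is
explicit: the brightest neuromelanin cluster is the SN; the darkest T2\*
cluster is iron-rich tissue. Laterality is split at the mid-sagittal plane
of the grid (first axis). Iron-rich connected components (26-connectivity,
components under 5 voxels discarded as speckle) are assigned per
hemisphere: of the two largest components, the more lateral centroid is
the SN, the more medial the RN; fewer than two per side is a diagnosed
segmentation failure. Neuromelanin volume is the number of VOI voxels with
normalized signal strictly above 1, times the voxel volume (0.6 × 0.6 ×
1.3 mm³ by default, so volumes land in the hundreds of mm³ for controls).

DAT-SPECT VOIs are defined once on the control-group ratio template —
labeled voxels with occipital-normalized ratio > 3 (caudate, putamen,
pallidum) or > 1.65 (brainstem) — and then applied to every subject. This
matters: patient putaminal ratios fall below the striatal threshold, so
thresholding per subject would empty the VOI precisely in the group of
interest. SBR is reported as mean VOI ratio − 1 (specific binding above
the nonspecific reference), the convention consistent with brainstem
values below 1; the thresholds above apply to the raw ratio.

## Radiomics conventions

Texture features are computed per VOI/contrast pair from the in-mask
voxels only. Intensities are discretized by uniform min–max binning into
32 gray levels (chosen to balance GLCM sparsity at SN voxel counts of a
few hundred; configurable). The GLCM pools co-occurrences over the 13
unique 3-D nearest-neighbour directions at distance 1, counts each pair in
both orientations (symmetry by construction), and normalizes to sum 1.
Feature definitions: contrast Σp(i,j)(i−j)², correlation
Σp(i,j)(i−μᵢ)(j−μⱼ)/(σᵢσⱼ), energy Σp², homogeneity Σp/(1+|i−j|).
Zero marginal variance makes correlation undefined; it is reported as 0
with a flag so feature tables stay numeric. First-order skewness and
kurtosis use plain 1/n central moments with the Pearson (non-excess)
kurtosis convention — a normal sample scores ≈ 3, matching the magnitude
of the package's calibrated control kurtosis values. Zero-variance samples
yield NaN shape statistics.

Each subject's MRI feature vector has 58 named entries: 6 texture features
for each of {NM-SN-L/R} on the neuromelanin map and {T2\*-SN-L/R,
T2\*-RN-L/R, NM-SN-L/R} on the T2\* map (48 texture features), plus 2
neuromelanin means, 2 neuromelanin volumes and 6 T2\* means.

## Statistics and classification

Group differences are per-feature one-way ANOVA (identical to the squared
two-sample t for two groups), reported with group means ± SD and raw
p-values; no omnibus multivariate test and no covariate adjustment is
implemented. LR correlations are Pearson, with Benjamini–Hochberg step-up
control at q = 0.05 applied to the correlation family only; degenerate
(zero-variance) features are excluded from the family. The high/low-risk
dichotomy uses LR > 50.

Classification z-scores features (population SD), optionally reduces by
PCA retaining the minimal component count whose cumulative explained
variance reaches 0.85 (MRI path; the SBR path uses the 7 features
directly), and evaluates decision trees, LDA, RBF-kernel SVM (C = 1, scale
gamma — the kernel is not dictated by the problem; linear is available via
the algorithms dict), logistic regression, k-NN, Gaussian naive Bayes and
a random forest under stratified fivefold cross-validation with a fixed
seed. Transforms are fitted inside each training fold (no leakage);
`paper_mode=True` reproduces the common GUI-tool workflow of fitting them
once on the full dataset. Metrics (pooled out-of-fold ROC-AUC, per-class
precision/recall, accuracy) select the best model by accuracy, which is
refit on all data for scoring held-out subjects such as phenoconverters.
Class imbalance (46 vs 29) is handled by stratification only.

## The phantom: what it emulates, and what it does not

Geometry is schematic: bilateral SN and RN are axis-aligned ellipsoids in
a box of 0.6 × 0.6 × 1.3 mm voxels, with a CSF-like aqueduct, a uniform
white-matter surround serving as the normalization reference, and a
midbrain working mask. Only contrast relationships matter for exercising
the algorithms. Tissue parameters per group: the SN carries a
neuromelanin first-echo contrast of 1.45 (controls) vs 1.37 (PD) — the
parameter is defined as the *observed* first-echo SN/WM ratio, so S₀ is
compensated for the differential T2\* decay accumulated by TE₁ — and an
iron-rich compartment at T2\* 30.67 vs 28.04 ms. The iron compartment is
medially shifted and slightly smaller than the neuromelanin extent, so
NM-defined and T2\*-defined SN VOIs overlap only partially (as in vivo),
and it does not shrink in disease: PD shortens its T2\* while the
neuromelanin extent scales by 0.88 linearly (the cube root of the ≈ 0.68
volume ratio between patient and control neuromelanin volumes). NMC sit
between the two (contrast 1.43, T2\* 30.0 ms, scale 0.97). RN T2\* is 26
ms in every group. Per-subject variability: 3% SD on contrast and size,
0.8 ms on T2\*, plus additive Gaussian noise (SD 1 against S₀ = 100).
Gaussian rather than Rician noise keeps the log-linear fit unbiased in
expectation at these SNRs, where the two are practically identical.

The DAT phantom paints each anatomical region's uptake at occipital ×
(1 + SBR), with SBR drawn per subject from the group's configured
mean ± SD (controls e.g. left putamen 3.38 ± 0.67, brainstem 0.79 ± 0.15;
patients 1.39 ± 0.40 and 0.64 ± 0.16) and small ratio-scale noise outside
the reference region, so the downstream normalization and ratio − 1
computation recover the configured group statistics. LR scores are drawn
(lognormal bulk, configurable tail above 50 of ≈ 13% for NMC and ≈ 3% for
NMNC), never computed from clinical scales.

The fast path (`generate_feature_table`) bypasses voxel data entirely and
draws all 58 MRI + 7 SBR columns as independent per-group Gaussians.
Thirteen MRI features and all seven SBR features carry group-specific
calibrated means/SDs; the remaining 45 columns use group-independent
values chosen per feature family (e.g. kurtosis ≈ 3, correlation ≈ 0.38,
energy ≈ 0.02 at 32 gray levels). A zero SD is allowed and yields constant
draws; a negative SD is a configuration error. Independence across
features is a deliberate simplification: real radiomics features are
strongly correlated within a VOI, so PCA on real data compresses harder
than on these tables, and passing classification benchmarks here
demonstrates correctness of the pipeline, not expected performance on
clinical cohorts. Likewise the image phantom omits scanner artifacts,
motion, registration error and partial-volume blurring, so segmentation
Dice values near 1 bound what the algorithm can do on clean input, not on
real anatomy. Because patient features are extracted inside control-defined
VOIs, image-path group means (e.g. a patient NM-SN mean of ≈ 1.21) sit
below the tissue-level calibration values — the VOI rim contains
background tissue in the group with the smaller structure, which is also
how the measurement behaves in vivo.

## Problem sizes and numerical choices

Default analyses are sized for a desk-scale workstation: demo cohorts of
~20 subjects for the end-to-end run, 6–8 controls per template, cohorts of
46 + 29 for the classification benchmarks with 20 simulation seeds, and
10³–2·10³ replicates for the statistical calibration suites. k-means uses
10 restarts with a seeded generator; ties and label permutations are
eliminated by centroid-order relabelling. All randomness flows from a
single integer seed through per-subject `SeedSequence` streams, so every
artifact is bit-reproducible.

## Known limitations

* No atlas parcellation, no registration, no acquisition physics; the
  phantom label maps and pre-aligned grids stand in for them.
* Mono-exponential, magnitude-only relaxometry; no multi-compartment fits
  or field-map correction.
* Only the six texture features plus mean and volume — no wavelet, shape
  or run-length families.
* No hyperparameter search; classifier defaults are fixed and documented.
* Feature-level simulations are Gaussian and independent across features.
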