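# Methods

`petrad` re-implements, as a tested and reusable pipeline, a PET-radiomics
analysis for predicting mid-term treatment response (complete metabolic
response vs not, by the Deauville 5-point scale) and prognosis (PFS/OS) in
high-risk diffuse large B-cell lymphoma. Because the underlying two-centre
patient cohort is not public, every stage is exercised on synthetic phantoms
and simulated cohorts with planted, known effect structure; the package's
claims are therefore *property* claims (oracle agreement, parameter
recovery, leakage-freedom), not patient-level reproductions.

## Imaging substrate and segmentation

PET volumes are 3-D grids of standardized uptake values (SUV) with physical
voxel spacing, default isotropic 4 mm (the reconstruction grid typical of
whole-body FDG PET). Lesion VOIs are grown semi-automatically: given a seed
region, the mask is the 26-connected component of voxels with
SUV >= 0.41 x SUVmax, where SUVmax is taken inside the seed region (a
`global_max` flag uses the volume-wide maximum instead; connectivity is
configurable). Lesions with metabolic tumor volume (MTV) below 10 cm^3 are
excluded — strictly smaller, so a 10.0 cm^3 lesion survives. Per-lesion
metrics are SUVmax, SUVmean, MTV (voxel count x voxel volume) and total
lesion glycolysis TLG = SUVmean x MTV. At patient level the feature VOI is
the union of retained lesions, SUVmax the maximum over lesions, MTV/TLG the
sums; whether radiomics should be computed on the largest lesion, per lesion,
or on the merged VOI is genuinely underdetermined in this analysis family,
and the merged-VOI choice is a documented default, not a claim.

## Feature catalogue

The extractor computes exactly 110 features in six families — 12 shape, 43
first-order (20 on continuous SUVs, 23 on the discretized intensity
histogram), 23 GLCM, 11 GLRLM, 5 NGTDM, 16 GLSZM — keyed as
`family.CODE.human_name` with the standard IBSI identifier codes so every
column is traceable. Choices a practitioner must make that the reference
formulas leave open:

- **Discretization**: fixed bin *number*, default 64, equal-width between the
  in-mask min and max (min -> level 1, max -> level Ng). A common PET
  radiomics default; exposed in `ExtractionConfig`.
- **Aggregation**: GLCM and GLRLM use the 13 unique 3-D directions at
  distance 1; features are computed per direction and averaged. GLSZM zones
  and NGTDM neighbourhoods are 26-connected over the whole VOI.
- **Degenerate conventions** (all tested): skewness/kurtosis/CoV of a
  constant VOI are 0; GLCM correlation of a constant VOI is 0; NGTDM
  coarseness is capped at 1e6; NGTDM busyness/strength with zero
  denominators are 0; histogram gradients of a single occupied level are 0.
  Any non-finite feature raises a named error — never a silent NaN.
- **Mesh-based shape**: volume and surface come from a marching-cubes
  triangulation of the mask at physical spacing. The binary indicator is
  anti-aliased with a one-voxel Gaussian before meshing: the raw binary
  iso-surface carries stair-step facets whose area does *not* converge to
  the smooth surface (about +10% on a digital sphere), while the smoothed
  0.5-level set recovers sphere volume and area to a few tenths of a
  percent. The cost is corner rounding on polyhedral shapes, an O(h) effect
  (about 4% on a 40-voxel cube). Voxel-counting ("approximate") volume is
  reported alongside. Single-voxel masks fall back to voxel-face counting.
- **Catalogue bookkeeping**: the source catalogue lists "Maximum 3D;
  Diameter" as two items but carries one identifier; it is read as the
  single feature *maximum 3D diameter* (a list-punctuation artifact), which
  preserves the count of 110. *Integrated intensity* (SUVmean x mesh volume)
  is intensity-weighted but kept under shape to match the printed grouping.
  One first-order identifier is printed twice (median / 50th percentile
  share a definition); the second occurrence is disambiguated as `Y12H1`.

Wavelet (single-level separable 3-D DWT, default `coif1`) and
Laplacian-of-Gaussian (default sigma 2 mm, physical units) transforms are
implemented and tested (perfect reconstruction, sub-band energy
conservation, linearity, zero response to constants), but the default
pipeline extracts features on the original image only: the catalogue total
of 110 equals the original-image catalogue, so filtered-image features are
off by default and flag-enabled (`ExtractionConfig.filtered_images`), with
the provenance tag prefixed to the feature name.

## Cross-combination engine and RadScore

Seven methods — GBDT, ET, RF, AdaBoost, LASSO, SVM, LR — serve both as
feature selectors and as classifiers, giving 49 pairs. For each pair,
stratified five-fold CV is run; *inside each training fold* the features are
standardized (training-fold statistics only) and recursively eliminated:
fit the selection model, record its inner-CV AUC on the current subset, drop
the lowest-weight feature (tree importances, or |coefficients| for the
linear methods), repeat to a single feature; the subset with the largest
inner-CV AUC wins, ties broken toward the smaller subset. The classifier is
then fit on the selected columns and scored on the held-out fold. The pair
with the largest mean held-out AUC is elected (ties broken lexicographically
in the method order above) and refit on the full training cohort; the
RadScore is the weighted sum of the selected standardized features, weights
from the classifier refit (selector weights behind a flag; an RBF-SVM
classifier has no per-feature coefficients, in which case selector weights
are used).

The published step order fits each selection model once on the whole
training cohort *before* the classifier CV; that order leaks selection
information into the folds, and the leakage-safe in-fold reading above is
the default. A `paper_protocol` flag reproduces the literal order for
comparison. The no-leakage property is tested directly: permuting the labels
drives every cell's AUC to chance.

Hyperparameters are fixed, light, and echoed into the run manifest
(ensembles at 50 trees, depth-2 GBDT, linear-kernel SVM as selector, RBF as
classifier, L1-logistic "LASSO" with a small CV-chosen penalty grid as
classifier and fixed C=1 as selector). The source analysis reports none; a
light fixed set keeps a 49-cell grid with in-fold selection tractable on one
CPU and makes runs reproducible. The elimination step is 1 feature per
iteration by default, configurable (the pipeline's `auto` step removes
~1/12th of the columns per iteration on wide tables).

The number of features the elimination retains is data-driven; the upstream
report itself is internally inconsistent about its key-feature count (11 in
one place, 10 in another), and the engine makes no attempt to force either.

## Synthetic data: what it emulates and what it does not

**Phantoms** are ellipsoidal lesions on a low-uptake background (default
SUV 1.0, Gaussian noise) with four texture generators — `uniform`,
`gaussian-noise`, `checker` (period in voxels), `radial-gradient` — chosen
to make texture families controllably discriminative. They emulate geometry,
contrast and texture, not scanner physics: no point-spread function,
attenuation, or reconstruction artifacts, so absolute feature values on real
scans will differ; what transfers is the correctness of the measurement
code, which is what the phantom tests establish. Voxel-counting MTV of a
digital sphere carries an O(h) surface discretization error (about 1-5% at
4 mm voxels depending on grid alignment).

**Cohorts** emulate the statistical shape of a 177-patient high-risk
cohort: twelve binary clinical covariates at the pooled printed marginal
frequencies; log-normal SUVmax/MTV/TLG calibrated so the printed
dichotomization fractions hold at the printed cutoffs (19.2 / 25.6 cm^3 /
222); a 110-column radiomic block of standard normals; a binary non-CR
outcome with log-odds planted on three key radiomic features plus male sex,
B symptoms and log-SUVmax (defaults 0.8/0.7/0.6 and 0.55/0.75/0.5); and
exponential PFS/OS times whose hazard is multiplied by exp(log 2.17) /
exp(log 2.14) in the high latent-score group, under administrative censoring
uniform on 18-42 months (median follow-up near 30 months) plus 10% early
dropout. The marginal non-CR prevalence defaults to 0.40 — the source
analysis does not print its rate; 30-40% of R-CHOP patients are
relapsed/refractory and this is a high-risk cohort, so the upper end is
used. The intercept is solved numerically so the realized prevalence matches.
Radiomic features are mutually independent, which real radiomic tables are
not; the cross-combination tests therefore demonstrate recovery of planted
independent signal, not behaviour under heavy collinearity.

The 7:3 split uses the ceiling convention for the held-out size
(ceil(0.3 x 177) = 54, train 123); plain rounding would give 124/53, which
does not match the printed cohort sizes.

## Clinical and survival layers

Youden cutoffs maximize J = sensitivity + specificity - 1 over midpoints of
consecutive distinct scores (predicted positive at score >= threshold; ties
go to the lower threshold) and are verified against exhaustive search. AUC
confidence intervals use DeLong-type structural-component variance.
Univariate/multivariate logistic models are maximum-likelihood fits
(statsmodels) reporting OR = exp(beta) with Wald CIs; perfect separation is
detected and raised, not silently diverged. The multivariate entry rule is
univariate p < 0.05. Five prediction models are built: combined (sex,
B symptoms, dichotomized SUVmax, dichotomized RadScore), clinical (sex,
B symptoms), PET (SUVmax), NCCN-IPI, IPI.

Calibration uses decile binning of predicted risk, averaged over bootstrap
resamples (the pipeline default is 200 repetitions; 1000 reproduces the
conventional figure at ~5x the cost; `reps=1` is the apparent curve), with
slope/intercept from regressing observed on predicted bin means. DCA uses
NB(p_t) = TP/n - (FP/n) p_t/(1-p_t) on a 0.01-0.99 grid, with treat-all and
treat-none references; the identities NB_perfect = prevalence and
treat-all(prevalence) = 0 are tested exactly. Nomogram points are
|beta| x range scaled so the largest effect spans 100 points, with the
total-points-to-risk map passing through the inverse logit so a nomogram
reading equals the model probability (tested to 1e-6).

Cohort-comparison chi-square is Pearson *without* continuity correction —
verified to reproduce the printed two-cohort p-values (sex 0.110, LDH 0.173,
B symptoms 0.250, bulky 0.851, RadScore group 0.947) from the printed
counts; correction is available behind a flag. The printed age-row p (0.132)
is not reproducible by an uncorrected Pearson test on its printed counts
(~0.16) and is excluded from checks.

Survival uses lifelines: product-limit KM curves (median = first time
S(t) <= 0.5, "not reached" reported as None), the standard log-rank test,
and Cox partial likelihood with Efron tie handling. The planted hazard
ratio near 2.17 is recovered on synthetic cohorts as an end-to-end
prognostic-logic check — pattern reproduction, not a patient-level value.

## Problem sizes and runtime

Tests and the acceptance script run on one CPU in minutes by scaling the
simulations: oracle sweeps use VOIs up to 6^3 voxels with 2-4 grey levels
(exhaustive enumeration is exact there and runs in seconds); selection
recovery uses 2 informative + 18 noise features at n = 600 over 10 seeds;
the full 49-cell grid demonstration uses the simulated 123-patient training
cohort with a 16-column radiomic subset (the three informative columns plus
noise); parameter-recovery cohorts use n = 4000-5000. The pipeline's `all`
command on the packaged demo configuration completes in a few minutes.

## Known limitations

- Not an IBSI certification: one discretization scheme, no 2-D variants,
  one aggregation convention per family.
- Synthetic cohorts have independent features and exponential hazards;
  real radiomic tables are collinear and hazards non-constant.
- The mesh smoothing that fixes sphere surface bias rounds sharp corners;
  shape features on deliberately polyhedral masks carry O(h) bias.
- Patient-level headline metrics (AUC 0.846/0.724 etc.) from the source
  cohort are out of reach by construction and are replaced throughout by
  recovery properties.
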