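# Methods

This note documents the models, algorithmic choices and numerical conventions
behind `radsubtypes`, and what the synthetic cohorts do and do not establish
about behavior on real data.

## Problem setting

Glioblastoma is radiologically heterogeneous. Given co-registered
multi-parametric MRI (mpMRI) — structural T1/T1CE/T2/FLAIR, diffusion-derived
AX/FA/RAD/TR, perfusion-derived rCBV/PH/PSR — and a segmentation of the tumor
into enhancing tumor (TU), non-enhancing core (NC) and peritumoral edema (ED),
the pipeline:

1. converts each subject into a fixed-length radiomic feature vector;
2. discovers imaging subtypes by stability-selected K-means clustering;
3. characterizes the subtypes by survival, spatial distribution and molecular
   composition;
4. tests whether radiogenomic signatures of EGFRvIII are sharper *within*
   subtypes than across the pooled cohort.

Patient mpMRI cohorts of this kind are generally not shareable, so the
package ships a synthetic cohort generator whose three planted archetypes
(rim-enhancing, irregular, solid) carry the qualitative contrasts the
pipeline is designed to recover. Every stage is exercised end-to-end on
generated cohorts.

## Synthetic cohort generator

**Geometry.** Tumors are built in a stylized atlas space: an ellipsoidal
brain parcellated into 9 regions (frontal, temporal, parietal, basal ganglia,
insula, cc/fornix, occipital, cerebellum, brain stem). A tumor is an
ellipsoidal core (semi-axes ~5 voxels, jittered ±15%) seeded at the deepest
point of the archetype's preferred region (frontal for rim-enhancing,
temporal for irregular and solid), split into an NC interior and TU shell,
and surrounded by an ED ring whose volume is `edema_scale` times the core
volume. The boundary is perturbed by a smoothed Gaussian random field with
amplitude `irregularity` (voxels). NC always keeps at least 15% of the core:
glioblastoma cores retain a substantial non-enhancing component, and letting
the perturbation erode NC to a handful of voxels would make the TU/NC ratio
feature degenerate.

**Intensities.** Normal-appearing brain is drawn as N(100, 25) in every
channel — the wide spread emulates CSF/GM/WM heterogeneity and, importantly,
anchors the per-subject percentile normalization on brain tissue rather than
on the (size-varying) tumor intensity tail. Each tumor subregion's voxels are
drawn from an archetype-specific Gaussian per (region, channel); the means
encode the qualitative contrasts: core TR (inverse cellularity proxy) ordered
rim > irregular > solid, rCBV (neovascularization) ordered solid > irregular
> rim, edema FLAIR (water density) highest in irregular, with edema size
irregular > rim > solid and boundary irregularity irregular > solid > rim.
Inter-patient variability is low-rank, as in real radiomic tables: each
subject draws a global intensity factor (SD 10 units, shifting every channel)
and three latent factors — vascularity (loads on rCBV, PH, T1CE, −PSR),
cellularity (loads on −TR, −AX, −RAD, FA) and edema water (loads on FLAIR,
T2) — plus an independent residual (SD 4) per (region, channel). Without this
spread archetype clusters would be unrealistically tight (see "Stability
selection" below). If a tail draw of the boundary-noise field erodes the core
below the minimum needed to split TU/NC, the geometry draw is
rejection-resampled deterministically within the subject's RNG stream.

**Clinical.** Survival is exponential with the archetype's median (19/12/6
months; rate ln2/median) — the simplest law fixed by a printed median and
sufficient for ordering and hazard-ratio recovery. Censoring is
administrative: with probability `censoring_fraction` (default 0.2) a subject
receives a censoring time uniform on [0, 3×median]; the observed time is the
minimum, so the realized censoring rate is somewhat below the nominal
fraction. Age is N(60, 10) years, independent of survival. EGFRvIII
prevalence is 12.5%/39.02%/30.61% per archetype; molecular-subtype mixtures
make proneural dominant in rim-enhancing, neural+mesenchymal in irregular and
classical in solid. Three biophysical growth parameters are drawn from
archetype Gaussians and passed through to the feature table.

**What the generator does not emulate:** MR physics (bias fields, partial
volume, scanner effects), multifocal disease, non-exponential survival,
informative censoring, registration error, or correlated feature noise.
Passing the planted-recovery suites shows the *pipeline machinery* is
correct; it does not validate the subtypes on real patients.

## Radiomic features (default catalog: 278)

* **Volumetric & shape (11):** ED/NC/TU volumes normalized by brain size,
  ED/(ED+NC+TU), TU/NC (missing when NC is empty), plus circularity and
  sphericity of NC, NC+TU, NC+TU+ED. Circularity `4πA/P²` uses the axial
  slice of maximal area, with area = voxel count and perimeter = exposed-edge
  count (4-connectivity); sphericity `π^(1/3)(6V)^(2/3)/A` uses exposed-face
  counts. These discrete estimators are exact for axis-aligned boxes (square
  → π/4, cube → (π/6)^(1/3)) but overestimate smooth boundaries — a
  rasterized disk converges to π²/16 ≈ 0.617 and a ball to 2/3, not 1 — so
  values are comparable across masks at one resolution but are not
  resolution-free. The tests pin both the box closed forms and the
  disk/ball limits.
* **Intensity (66):** mean and population SD per (subregion, channel).
* **Histogram (165):** each channel is normalized per subject to [0, 1] by
  clipping at the 1st/99th percentile of in-brain intensities and min-max
  scaling; each (subregion, channel) yields the percentage of voxels in 5
  equal-width bins (right-open, last bin closed). The natural count is
  5 × 11 × 3 = 165; the catalog accepts an exclusion list for variants that
  drop specific bins.
* **GLCM texture (24):** 6 measures × 4 structural channels over the whole
  tumor (TU∪NC∪ED) — the only natural product equal to the intended 24.
  In-mask intensities are quantized to 32 equal-width levels over the
  region's own range (constant region → level 0); for each of the 26 nonzero
  sign-vector directions and distances 1 and 2 voxels, a symmetric
  co-occurrence matrix is accumulated over voxel pairs lying both inside the
  mask; energy (Σp²), contrast, entropy (natural log), correlation,
  dissimilarity and homogeneity (1/(1+(i−j)²) weight) are averaged over all
  matrices with at least one pair. Constant regions give energy =
  homogeneity = 1, contrast = entropy = dissimilarity = 0 and missing
  correlation. The implementation is verified against a brute-force pair
  enumeration oracle to 1e-10.
* **Location (9):** percentage of tumor core (TU∪NC) per atlas region.
* **Growth (3):** pass-through from the clinical table.

Missing values (empty NC, unknown growth parameters) are imputed by the
per-feature cohort median before scaling; the imputation mask is kept.

## Subtype discovery

Features are min-max scaled to [0, 1] on the discovery cohort; replication
data are scaled with the *discovery* parameters and deliberately not clipped.
For each K in 2..6, K-means is run many times (default 1000; Lloyd
iterations, Euclidean metric, uniform random selection of K subjects as
initial centroids, tolerance 1e-6, max 300 iterations; each run keeps the
best of 3 random starts by inertia) and ensemble stability
is the average adjusted Rand index over all unordered run pairs — computed
exactly by grouping identical partitions, so cost scales with the number of
distinct partitions rather than run pairs (a pair-subsampling switch exists
for very diverse ensembles). The chosen K maximizes average ARI (ties to the
smaller K).

The representative assignment groups runs into equivalence classes
(identical partitions up to relabeling); among classes holding at least 20%
of runs, the one with the highest mean silhouette wins; if none reaches 20%,
the most frequent class is used and a warning emitted. Cluster display names
(rim-enhancing / irregular / solid) are assigned post hoc from centroid
signatures (edema-fraction and core-rCBV orderings) and are purely cosmetic.

A structural note on stability selection and optimizer strength. With
single-start random initialization the probability that one initialization
covers all three planted clusters is about 6/27, and Lloyd escapes a bad
start only when clusters overlap appreciably; very tight clusters then
*lower* run-pair agreement (runs freeze in diverse local optima), while at
K+1 any two runs sharing the K-cluster backbone agree on most item pairs,
inflating the K+1 average. The opposite failure occurs with a very strong
optimizer (many starts per run): every run resolves to the identical best
partition at every K, all averages saturate at 1.0, and the selection rule
degenerates to its tie-break. Stability selection is informative only when
the optimizer is imperfect enough for run-to-run variation to reflect how
contested each K is; the default of 3 starts per run, together with the
generator's low-rank inter-patient variability, places the planted cohorts
in that regime (K = 3 average ARI ≈ 0.97–0.99, K = 2 ≈ 0.76–0.95,
K = 4 ≈ 0.84–0.89 across cohort seeds).

Reproducibility is quantified two ways: 10-fold cross-validation (re-cluster
9 folds, assign the 10th by nearest training centroid, align training
clusters to the full-data reference by maximum-agreement matching, pool the
held-out agreement percentage; per-fold ensembles default to 100 runs for
speed) and replication-cohort assignment by nearest centroid in the
discovery-scaled space (distance ties, which have probability zero for
continuous features, go to the lowest cluster index).

Per-feature association with subtypes uses Kruskal–Wallis with tie
correction and Bonferroni adjustment (α = 0.05).

## Survival analysis

Kaplan–Meier curves use the product-limit estimator; the reported median is
the smallest observed time with S(t) ≤ 0.5 (left endpoint of any flat
interval at exactly 0.5), undefined when S never reaches 0.5. Group
comparison uses the Mantel–Cox log-rank test. Cox models are fit by partial
likelihood (lifelines); synthetic survival times are continuous so tie
handling is immaterial. Subtypes enter as K−1 indicators with rim-enhancing
as the reference; the 9 location percentages are compositional (rows sum to
100), so one region is dropped from Cox designs to keep them non-singular.

Harrell's c-index counts pairs in which the earlier time carries an event;
concordance means the shorter survival has the higher risk score; score ties
count 0.5. Its p-value against 0.5 uses a normal approximation with variance
c(1−c)/N over N comparable pairs (Noether-style; ignores pair correlation —
adequate for the screening use here). The six-configuration comparison (age |
location | subtype | subtype+age | subtype+location | all three) reports
apparent (in-sample) c-indices, as the source analyses do; a held-out variant
is a caller-side loop away but not part of the default report.

A sampling caveat on Kaplan–Meier medians: under the exponential survival law
the KM median of a ~200-subject arm has a sampling SD of roughly 10% of the
true median (Monte Carlo: SD 1.97/1.31/0.60 months for medians 19/12/6 with
the default censoring). A "within 15%" check on one cohort is therefore a
~1.4σ event per arm and holds jointly for all three arms in only ~60% of
cohorts; the estimator is unbiased, and ordering/hazard-ratio recovery is far
more robust than point-median recovery at this scale.

## Spatial maps

The subtype probability map at voxel i is the fraction of the subtype's
tumors (core = TU∪NC) covering i; values are exact multiples of 1/n. Regional
proportions re-use the location-feature implementation. Masks must already
share the atlas grid; the generator produces data directly in atlas space,
and real-data users must supply pre-registered masks.

## Radiogenomics

Univariate: Cohen's d with pooled SD, |d| per feature within each subtype and
pooled; subjects with unknown mutation status are excluded; strata smaller
than 4 known-status subjects (or with a group below 2) are omitted with a
warning.

Multivariate: per-subtype RBF-SVM classifiers versus one pooled classifier.
Evaluation is stratified k-fold CV (default 5 folds, reduced automatically
when the minority class is small). Inside each training fold only: greedy
sequential forward selection scored by inner-CV accuracy (stop when accuracy
stops improving, patience 1, max 15 features), then a small grid search over
C ∈ {0.1, 1, 10} and kernel width ∈ {scale, 0.01, 0.1}. A dedicated test
poisons held-out rows and asserts the selected features and hyperparameters
are unchanged (leakage check). The rim-enhancing subtype is handled by a null
model that predicts every subject mutation-absent (its low prevalence makes
that the intended baseline); its accuracy equals the fraction truly absent.
The within-subtype summary accuracy is always total correct / total
classified across strata — never the unweighted mean of stratum accuracies —
and this aggregation is asserted against exact rational arithmetic.

Subtype × molecular-subtype composition uses Pearson's χ² (no continuity
correction), df = (r−1)(c−1).

## Problem sizes and numerical conventions

Default test/verification sizes, chosen to exercise each property at the
smallest scale where it is statistically meaningful: planted-recovery cohort
n = 120 (balanced, 40³ voxel volumes, 200-run ensembles; per-fold CV
ensembles 100 runs), survival cohort n = 600 (clinical + location only,
streamed), radiogenomic planted tables n = 300 with 20 features and effect
size 1.5 over 20 seeds, GLCM oracle volumes ≤ 12³, exhaustive ARI oracle over
all partitions of ≤ 6 items plus a seeded sample at 7 (the full 7-item pair
enumeration costs minutes for no additional coverage). All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; cohort
generation, clustering and classification are bit-reproducible given (spec,
seed).

## Known limitations

* Discrete perimeter/surface estimators bias circularity/sphericity of
  smooth shapes (documented limits above); fine for cross-subject contrast at
  fixed resolution, wrong for absolute shape comparison across resolutions.
* Average-ARI model selection depends on calibrated optimizer imperfection
  (see above): on very tightly separated data a weak optimizer can prefer
  K+1 and a strong one saturates every K at 1.0. K selection should always
  be read together with the representative assignment and CV
  reproducibility.
* KM point-medians on a few hundred subjects carry ~10% sampling error;
  single-cohort median checks are stochastic even when the generator is
  exactly correct.
* Apparent c-indices are optimistic relative to held-out evaluation.
* The synthetic generator's independence assumptions (independent Gaussian
  intensities, independent censoring, survival independent of age) make the
  planted-recovery results a correctness check of the machinery, not a
  biological validation.
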