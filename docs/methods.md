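# Methods

`crossmodal_rsa` implements a representational similarity analysis (RSA)
pipeline for asking whether two presentation modalities of the same concepts
— here spoken words and signs, each produced by two different people
("language models": speaker 1/2, signer 1/2) — evoke shared or
modality-specific neural codes.  The pipeline starts from first-level GLM
outputs (per-run condition betas and residual frames on a voxel grid) and
ends with labeled regional verdicts.  Everything upstream of the betas
(slice-timing, realignment, normalization, HRF-level GLM fitting) is out of
scope by design.

## Condition space and cell masks

The design crosses 9 items (3 per semantic category: fruit, animals,
transport) with 2 modalities and 2 producers, giving 36 conditions.  RDMs
(representational dissimilarity matrices) are stored over the 630 unordered
condition pairs in a fixed canonical order: modality-major, producer next,
item last.  Analyses are restricted by *cell masks*:

- `within_speech_across_speaker` / `within_sign_across_signer` (81 cells
  each): within-modality pairs crossing producers, so that low-level
  acoustic/visual similarity between identical tokens cannot drive a fit;
- `within_modality_combined` (162): their union;
- `across_modality` (324): every speech x sign pair;
- `within_modality_all(m)` (153): all pairs within one modality, including
  same-producer pairs — the producer-identity models are constant without
  them.

## Crossnobis distances with multivariate noise normalization

The spatial noise covariance is estimated per run from residual frames
(population 1/N convention, frames demeaned per run), shrunk toward its
diagonal with an analytic Ledoit–Wolf-type intensity (the ratio of summed
sampling variances of the off-diagonal entries to their summed squares,
clipped to [0, 1]), and averaged over runs.  Patterns are prewhitened by the
inverse symmetric square root.  The cross-validated Mahalanobis (crossnobis)
distance for conditions i, j over P voxels and R runs is

    d(i,j) = 1/(P R (R-1)) * sum_{m != n} (b_i^m - b_j^m)' S^-1 (b_i^n - b_j^n).

Cross-validation across runs makes the estimator unbiased: zero means "no
pattern difference", individual cells may be negative, and mean distances
can be tested directly against zero.  The 1/P normalization (the choice is
ours; it does not affect rank-based model fits) keeps distances comparable
between searchlight spheres truncated at mask edges.  All 36 conditions
enter every RDM; masking to cell subsets happens at fit time.

## Model RDMs

- **Semantic feature model** — cosine distance between the items'
  concept-feature vectors, tiled over the masked cells (same-item cells
  predict 0).  The exact transform from norms to dissimilarities is a free
  choice; cosine on feature vectors is standard and only ranks matter
  downstream.
- **Item model** — 0 for same-item cells, 1 otherwise: each concept is
  uniquely represented, with no graded relatedness.
- **Category model** — the feature model's predictions with all same-item
  cells removed from the tested mask: between-item semantic structure only.
  Together the item and category models decompose the feature model.
- **Producer identity models** — over `within_modality_all(m)`: 0 for
  same-producer pairs, 1 for different-producer pairs; a probe for residual
  low-level acoustic/visual coding.
- **Iconicity model** — |rating_i − rating_j| on the 1–7 scale.
- **Phonological distance** — Levenshtein distance over phoneme sequences
  divided by the longer word's phoneme count (computed with edlib after
  mapping phoneme symbols to a private alphabet).  Used, with plain Pearson
  correlation between candidate models (`model_correlation`), to screen
  that phonemic or iconicity structure does not mimic the semantic model.

## Inference

Model fits use **Kendall's tau-a** — (concordant − discordant) /
(m(m−1)/2) over all cell pairs, ties counting as neither — because the
models are full of tied predictions.  A quadratic reference implementation
and an O(m log m) path (recovering the integer concordant−discordant
balance from the tie-corrected tau-b) agree exactly and are both exposed.
Tau is converted to a Pearson-scale r by Greiner's relation
r = sin(pi·tau/2) and Fisher-transformed (|r| clamped at 1−1e−12 so perfect
fits stay finite).  Group tests are ordinary t tests on the z values:
one-tailed against zero for model fits (negative fits to a dissimilarity
model are not meaningful), two-tailed paired for fit differences.
Significance thresholds divide the base alpha by the number of
regions/tests and round half-up to 3 decimals (0.05/6 → 0.008, /3 → 0.017,
/4 → 0.013, /5 → 0.010).

**Noise ceilings** bound the fit any model could achieve given
between-subject inconsistency: the lower bound correlates each subject's
RDM with the leave-one-out group mean, the upper bound with the grand mean,
both on the z scale, per cell mask.

**Verdict logic** (`classify_region`): a region is labeled
`shared-semantic` when the category model fits both within and across
modality; `modality-form` when there is item-level structure within a
modality together with producer-identity sensitivity and no across-modality
category fit; `none` otherwise.

## Searchlight mapping and cluster inference

A spherical searchlight enumerates all integer voxel offsets within the
physical radius (65 voxels at 8 mm on a 3×3×4 mm grid).  At each center the
sphere's crossnobis RDM is computed — noise covariance estimated from the
sphere's residual frames; the shrinkage intensity is evaluated analytically
on ~20 sampled spheres and its median reused, since its sphere-to-sphere
variation is negligible against its sampling noise — and the mean of each
requested cell mask is written to the center voxel.  Spheres truncated by
the brain mask are kept when ≥50% of their offsets are in-mask.  Per-center
RDMs are retained so clusters can later be summarized without a second pass.

Group inference: voxelwise one-sample (greater-than-zero) or paired t maps;
threshold at the t quantile of the cluster-forming p (default 0.005);
connected components under 18-connectivity (faces + edges); cluster-level p
from a sign-flip permutation null of the maximum cluster extent;
Benjamini–Hochberg FDR across clusters at q (default 0.05).  Permutation
inference replaces parametric random-field cluster statistics: it is exact
under the sign symmetry of the null and needs no smoothness estimate, so
published random-field extent thresholds are not comparison targets.

## ROIs, leave-one-out families, and the orthogonality guard

Surviving clusters become ROIs; a subject's ROI RDM is the cellwise mean of
the searchlight RDMs centered inside it (center-based membership).  Because
ROIs are selected for large mean distance over the across-producer cells,
any model predicting a mean shift on exactly those cells would be tested
circularly.  Rank correlation removes the mean of the tested cells, so
models whose predictions do not co-vary with membership in the selection
set are safe; the guard computes exactly that correlation and flags
violators (the identity models).  Those are fit only in
leave-one-participant-out ROIs: for each subject the group map is
re-estimated from the other n−1 subjects, thresholded at p < 0.001
uncorrected, and its components form that subject's ROI family; families
are matched to full-group clusters by maximal Dice overlap.

## Non-metric MDS

Group-average RDMs are embedded by non-metric MDS (scikit-learn, monotone
regression, Kruskal stress-1, best of 10 seeded restarts).  Crossnobis cells
can be negative, so off-diagonal cells are shifted by their minimum first —
rank-preserving, hence harmless under a non-metric treatment.  Category
centroids average the 6 embedded conditions (3 items × 2 producers) per
category per modality.

## The synthetic cohort generator

The generator produces what the analysis consumes — betas + residuals —
rather than simulating time series: noise is injected at the beta level with
matched residual frames from the identical process, so the covariance the
estimator sees is the covariance that corrupted the betas.  Noise is a white
Gaussian field smoothed with a configurable FWHM (default 6 mm, circular
boundary so the field is stationary) and rescaled to an exact marginal sd
(default 1.0 beta units).

Signal lives in disjoint regions, each with one archetype of planted
geometry built from frozen Gaussian component patterns:

    b(item, modality, producer) =
        a_cat * P_sem(category)                  # modality-invariant
      + a_item_within[mod] * P_item^mod(item)    # per-modality item code
      + a_item_shared * P_item(item)             # modality-invariant item code
      + a_id[mod] * P_id(mod, producer)          # producer identity
      + a_item_cross * s(mod) * Q(item)          # antisymmetric: s=+1 speech, -1 sign

`shared_semantic` sets a_cat = a_item_within = a_item_cross = strength;
`speech_form` sets a_item_within and a_id for speech only; `sign_form`
mirrors it; `null` is all zeros.  Two departures from the plainest possible
component model deserve explanation:

- **Graded category geometry.**  When feature norms are supplied, the
  category component encodes unit-norm *category feature profiles* (mean
  member vector per category) through a random linear map, so expected
  between-category pattern distances are proportional to the profiles'
  cosine distances rather than uniform.  Real feature-based codes are
  graded in exactly this way.
- **The antisymmetric item component** (speech +Q, sign −Q) cancels out of
  every within-modality comparison but raises same-item across-modality
  distances to the unrelated-item level.  Without it, any categorical
  shared code mechanically leaves same-item cells lowest (same item implies
  same category), and the item model — statistically efficient because of
  its tie structure — fits across modality at every amplitude where the
  category fit is detectable.  The empirical archetype being emulated is
  precisely *category without item* cross-decoding: a concept's spoken and
  signed forms are no more similar than two arbitrary same-category
  concepts.

Subjects share the planted layout but not its exact instantiation:
each subject's component draws correlate with the cohort-level draws at
`subject_pattern_corr` (default 0.75), plus a per-region lognormal
amplitude jitter (log-sd 0.2).  Fully shared geometry
(`subject_pattern_corr = 1`) makes every finite-voxel quirk of the planted
patterns common to all subjects, which group t tests then treat as signal
with near-zero variance — effect sizes become implausibly large and noise
ceilings pin near maximum.  Subject-unique pattern variance is also what
makes noise ceilings informative.

**Defaults as study conditions.**  17 subjects, 6 runs, 3×3×4 mm voxels,
100 residual frames per run, 2 repetitions of each of the 36 conditions per
run.  The default planted strength (0.08 beta units against noise sd 1.0)
was fixed once, before the acceptance tests were written, by a realism
criterion: group-level effect sizes of the primary fits in the planted
regions should land in the d_z ≈ 0.5–2 range that real studies of this kind
report, rather than the d_z > 5 that stronger plants produce.  At these
conditions the shared/modality-specific dissociation is recovered reliably
across seeds.

The generator also emits the trial-level design — per run 91 trials: 72
core (each condition twice, as two randomized mini-blocks with no concept
repeated back-to-back), 6 target fillers, 6 non-target fillers and 7 nulls,
the 19 non-core trials stratified-randomly over the run — and synthetic
binary concept-feature norms with category-shared, cross-category-shared
and item-unique feature blocks.  Durations use the measured mean stimulus
lengths (speech 0.558 s, sign 1.107 s, null 4 s).  The first-level design
matrix itself is never constructed (the pipeline starts at betas), so the
regressor bookkeeping of the original acquisition is not reproduced here.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: haemodynamics and GLM estimation error
correlations between betas, subject-specific anatomy and normalization
error (all subjects share one grid), physiological noise structure beyond
stationary spatial smoothness, motion, and real concept-norm feature
statistics.  Recovery results demonstrate the pipeline's correctness and
calibration, not empirical claims about brains.

## Numerical choices and degenerate inputs

- Covariances: population (1/N) convention; singular estimates are flagged
  and rejected at use with a pointer to shrinkage.
- tau-a: constant models are rejected (no rank variation); fully tied data
  gives tau 0.
- z clamping at |r| = 1−1e−12; `adjust_alpha` rounds half-up to 3 decimals.
- Cluster p values use the add-one permutation convention
  (1 + #{extent ≥ obs}) / (n_perm + 1).
- Empty suprathreshold sets yield empty cluster tables and empty ROI
  families with warnings, not errors; two-subject leave-one-out requests
  warn and return empty families.
- Sphere centers need ≥50% in-mask offsets; searchlight maps are NaN
  elsewhere, and group maps propagate NaN and flag zero-variance voxels.

## Problem sizes used in the test and acceptance runs

Simulated scenes in the shipped tests use reduced grids (8×8×4 to 12×12×8
voxels, 4–6 runs, 30–60 residual frames, searchlight radius 5 mm) so the
full discovery → ROI chain, a 200-repetition null calibration of the
cluster family-wise error rate, and the 17-family leave-one-out
reconstruction all run comfortably on one CPU.  These sizes are the
package's chosen reference conditions for its own verification; the
pipeline itself is size-agnostic.

## Known limitations

- The verdict logic is a faithful but coarse encoding of the published
  decision criteria; borderline regions near the adjusted alpha flip labels.
- Iconicity item-level ratings are synthetic (category means are matched;
  see `data/iconicity_synthetic.csv`).
- The orthogonality guard reasons about mean shifts only; selection effects
  through higher moments are not modeled (none of the standard models
  produce any).
- Leave-one-out ROI matching by spatial overlap can return no match for a
  weak family; such subjects drop out of identity-model group tests.
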