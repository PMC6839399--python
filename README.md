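# crossmodal-rsa

Representational similarity analysis (RSA) of shared and modality-specific
conceptual codes in multivariate brain-imaging data.

When the same concepts are presented in two modalities — e.g. spoken words
and signs, each produced by two different speakers/signers — does a brain
region encode them with a common semantic geometry, or with
modality-specific word/sign form codes?  This package implements the full
analysis chain for that question, for researchers working with fMRI
multivariate pattern data (or synthetic stand-ins):

- **Crossnobis RDMs**: cross-validated Mahalanobis distances between
  condition patterns with multivariate noise normalization,
  `d(i,j) = 1/(P·R(R−1)) Σ_{m≠n} (b_i^m − b_j^m)ᵀ Σ̂⁻¹ (b_i^n − b_j^n)`,
  an unbiased estimator with an interpretable zero;
- **Searchlight mapping** of mean masked distances (e.g. within-modality,
  across-producer cells only) with sign-flip permutation cluster inference
  (cluster-forming p < 0.005, FDR q < 0.05 on cluster extent);
- **Model RDMs**: semantic feature (cosine distances over concept property
  norms), its decomposition into item and category models, speaker/signer
  identity models, iconicity and normalized phoneme edit distance;
- **Tau-a model fitting**: Kendall tau-a (tied ranks handled by design),
  converted via Greiner's relation `r = sin(π·τ/2)` and Fisher's z to
  permit one-tailed one-sample and two-tailed paired t tests, with
  leave-one-out / grand-mean noise ceilings;
- **Leave-one-participant-out ROIs** with an orthogonality guard, so
  identity models are never tested in the data that selected the region;
- **Non-metric MDS** visualization with category centroids;
- a **synthetic cohort generator** that plants shared-semantic,
  speech-form, sign-form, and null representational geometries in known
  voxels, so the whole chain is testable end to end without any scanner
  data.

## Worked example

Simulate a 17-subject cohort (12×12×8 grid, 3×3×4 mm voxels, 6 runs) with
four planted regions, run the within-modality searchlight, cluster
inference, and ROI model fitting:

```python
import crossmodal_rsa as cr
from crossmodal_rsa.io import RunConfig
from crossmodal_rsa.pipeline import run_discovery_pipeline
from crossmodal_rsa.simulate import generate_feature_norms

cfg = RunConfig(n_subjects=17, n_runs=6, dims=(12, 12, 8),
                n_residual_frames=60, radius_mm=5.0,
                n_permutations=300, seed=11)
space = cr.build_condition_space()
norms = generate_feature_norms(space, seed=11)
cohort, sl, disc, analyses = run_discovery_pipeline(cfg, norms)
print(disc.clusters.table[["cluster_id", "extent", "p", "q_value", "survives"]])
```

```
 cluster_id  extent        p  q_value  survives
          1      81 0.003322 0.011074      True
          3      49 0.006645 0.011074      True
          5      49 0.006645 0.011074      True
          4       3 0.431894 0.539867     False
          2       1 0.903654 0.903654     False
```

Three clusters survive — one per planted signal region; the zero-amplitude
region produces nothing.  Each surviving cluster's ROI analysis fits the
model battery on the cluster-averaged crossnobis RDMs (alpha 0.05/3 = 0.017
for three clusters).  The cluster over the planted shared-semantic region:

```
within_modality_combined_1: verdict=shared-semantic (alpha=0.017)
  category_within  t=  4.84  p=0.0001  d_z= 1.18  ceiling=(0.20, 0.37)
  category_across  t=  4.25  p=0.0003  d_z= 1.03  ceiling=(0.12, 0.32)
  item_within      t= 13.26  p=0.0000  d_z= 3.22  ceiling=(0.34, 0.48)
  item_across      t= -4.41  p=0.9998  d_z=-1.07  ceiling=(0.17, 0.35)
```

Categories cross-decode between modalities (category model fits within
*and* across), while items do not (item model fits within only) — the
signature of a shared but coarse semantic code.  The cluster over the
planted speech-form region instead shows item and speaker-identity fits
with no across-modality category structure (`verdict=modality-form`), the
identity model being evaluated in leave-one-participant-out ROIs because it
is not orthogonal to how the region was selected.  `t` and `d_z` are the
group t statistic and within-subject effect size of the Fisher-z model
fits (df = 16); `ceiling` brackets the best fit any model could achieve
given between-subject inconsistency.

The same chain is scriptable from the shell:

```bash
crossmodal-rsa simulate   --config cfg.yaml
crossmodal-rsa searchlight --config cfg.yaml
crossmodal-rsa cluster    --config cfg.yaml
crossmodal-rsa roi-fit    --config cfg.yaml
crossmodal-rsa report     --config cfg.yaml
# or everything at once:
crossmodal-rsa pipeline   --config cfg.yaml
```

Stimulus-side distances with the packaged phoneme transcriptions and
synthetic iconicity ratings (`crossmodal-rsa stimdist --out out --seed 1`):

```
       model  r_vs_semantic        p  n
phonological      -0.143891 0.402452 36
   iconicity      -0.051405 0.765901 36
```

— neither phonemic form nor iconicity mimics the semantic feature
distances over the 36 item pairs, so they are safe to test as separate
models.

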