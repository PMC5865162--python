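# radsubtypes

Radiomic subtype discovery for glioblastoma multi-parametric MRI (mpMRI):
a self-contained re-implementation of the analysis pipeline behind the
three-subtype radiomic signature of glioblastoma — feature extraction,
stability-selected K-means subtyping, survival and spatial characterization,
and within-subtype radiogenomics — together with a synthetic mpMRI cohort
generator so the entire pipeline runs and is tested end-to-end without any
patient data.

## The scientific problem

Glioblastoma looks radically different across patients on MRI, and that
heterogeneity carries prognostic and molecular information. Given
co-registered mpMRI channels (structural T1/T1CE/T2/FLAIR, diffusion-derived
AX/FA/RAD/TR, perfusion-derived rCBV/PH/PSR) and a tumor segmentation into
enhancing tumor (TU), non-enhancing core (NC) and peritumoral edema (ED),
the pipeline:

1. **extracts a 278-feature radiomic vector per subject** — volumetric and
   shape (11), intensity (66), histogram (165), GLCM texture (24), atlas
   location (9), and biophysical growth pass-throughs (3);
2. **discovers imaging subtypes** by K-means stability selection: for each
   candidate K, many K-means runs from random initializations are compared
   by average pairwise adjusted Rand index (ARI); the most stable K wins and
   the highest-silhouette recurring partition becomes the subtype
   assignment. The discovered subtypes are *rim-enhancing*, *irregular* and
   *solid*;
3. **characterizes the subtypes** by Kaplan–Meier/log-rank/Cox survival
   analysis (subtypes carry distinct prognoses), voxel-wise spatial
   frequency maps, and molecular composition;
4. **tests the radiogenomic claim** that an EGFRvIII mutation signature is
   classified more accurately *within* imaging subtypes than on the pooled
   cohort (nested RBF-SVM with sequential forward feature selection, fully
   leakage-free).

Real patient cohorts of this kind are not shareable, so the package ships a
synthetic generator (`radsubtypes.synthetic`) whose three planted archetypes
carry the published qualitative contrasts — intensity orderings, edema and
irregularity orderings, survival medians 19/12/6 months, EGFRvIII
prevalences 12.5%/39.0%/30.6% — making every downstream stage testable
against known ground truth. See `docs/methods.md` for the full model,
numerical conventions and limitations.

## Worked example

```python
from radsubtypes.synthetic import CohortSpec, generate_cohort, make_atlas
from radsubtypes.features import extract_feature_table
from radsubtypes.clustering import ImagingSubtyper
from radsubtypes.survival import km_estimate

spec = CohortSpec(n_subjects=60, random_seed=7)
studies, clinical = generate_cohort(spec)
atlas = make_atlas(spec.volume_shape)

table = extract_feature_table(studies, atlas)
print("feature table:", table.frame.shape)

subtyper = ImagingSubtyper(k_range=(2, 3, 4, 5, 6), n_runs=100, random_state=7)
subtyper.fit(table)
print("selected K:", subtyper.k_)
print("average pairwise ARI per K:",
      {k: round(v, 3) for k, v in subtyper.k_report_.average_ari.items()})
print("cluster names:", subtyper.cluster_names_)

clinical = clinical.assign(
    subtype=[subtyper.cluster_names_[c] for c in subtyper.labels_])
for name, group in clinical.groupby("subtype"):
    print(f"{name}: n={len(group)}, KM median survival "
          f"{km_estimate(group).median:.1f} months")
```

Output (~1 minute on one CPU; exactly reproducible):

```text
feature table: (60, 278)
selected K: 3
average pairwise ARI per K: {2: 0.903, 3: 0.953, 4: 0.765, 5: 0.713, 6: 0.711}
cluster names: ['rim_enhancing', 'solid', 'irregular']
irregular: n=25, KM median survival 8.0 months
rim_enhancing: n=23, KM median survival 16.8 months
solid: n=12, KM median survival 3.6 months
```

Stability selection recovers the planted K = 3; the cluster display names
are derived post hoc from centroid signatures; survival ordering
(rim-enhancing > irregular > solid) is recovered, with the point medians at
n = 60 carrying the expected sampling noise.

The same pipeline is available from the command line
(`radsubtypes --help`): `simulate`, `extract`, `cluster`, `assign`,
`survival`, `spatial`, `radiogenomics`, or `all` to run the chain on one
output directory, reading/writing NIfTI volumes and CSV tables.

## Repository layout

```
src/radsubtypes/
  synthetic.py       # archetypes, atlas, cohort generator, clinical draws
  features.py        # 5-family feature catalog + extraction (incl. 3D GLCM)
  clustering.py      # scaling, ARI, K-means ensembles, stability selection,
                     # ImagingSubtyper estimator, SubtypeModel persistence
  survival.py        # KM, log-rank, Cox, Harrell c-index, model comparison
  spatial.py         # subtype probability maps, regional summaries
  radiogenomics.py   # effect sizes, SFS + RBF-SVM within vs pooled, chi-square
  io.py, cli.py      # NIfTI/CSV/JSON round-trips and the click CLI
tests/               # unit + property + acceptance suites (oracle-first)
scripts/acceptance.py
docs/methods.md      # model documentation and numerical conventions
```
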