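# aneufuse

Multidimensional feature fusion for intracranial-aneurysm rupture-risk
estimation.

Rupture of an intracranial aneurysm causes subarachnoid hemorrhage, a
catastrophic event with high mortality; assessing the rupture risk of an
incidentally discovered aneurysm from angiographic imaging is a central
clinical problem. `aneufuse` implements a complete machine-learning
pipeline for this task, aimed at researchers working with cohorts of
segmented aneurysms (angiographic volume + binary mask + surface mesh +
clinical record per case):

* **Morphometrics** — 25 features from the surface mesh: oriented-bounding-
  box length/width/height, surface area, enclosed volume, and
  {max, min, mean, std} of the discrete principal (κ₁, κ₂), Gaussian
  (K = κ₁κ₂), mean (H = (κ₁+κ₂)/2) and curvedness (√((κ₁²+κ₂²)/2))
  curvatures (angle-deficit / cotangent-Laplacian estimators).
* **Radiomics** — the standard 107-feature battery on the volume/mask pair
  after 0.5 mm isotropic resampling and [0, 100] intensity rescaling:
  18 first-order, 14 shape-3D, and texture features from five matrix
  families (GLCM 24, GLRLM 16, GLSZM 16, NGTDM 5, GLDM 14), each formula
  implemented from its definition.
* **Deep-feature transforms** — the three output transforms of a pluggable
  two-score CNN extractor (raw / sigmoid / binarized at 0.5), with a
  deterministic stub extractor for pipeline testing.
* **Consensus feature selection** — per-fold random-forest and
  gradient-boosting importances; Step 1 unions the per-fold intersections
  into M, Step 2 ranks M by accumulated importance and intersects the
  per-method top halves: N = M_r ∩ M_x.
* **Nested evaluation** — stratified 8-fold outer cross-validation with
  exhaustive inner grid search (7-fold, scored by mean F2) over five
  classifiers (SVM, LR, RF, XGBoost, KNN); reports per-fold and mean
  F2 = 5PR/(4P+R), accuracy, AUC (Mann–Whitney pair count), precision,
  recall and a mean ROC curve. Scaler, selection and grid search are fitted
  on training folds only.
* **Phantom cohorts** — a synthetic generator (lobulated ellipsoid lesions
  with matching volume, mask, watertight mesh, clinical record and a
  planted morphology→rupture label signal) so every stage is testable
  without clinical data.

## Worked example

Generate a 32-case phantom cohort and run the full pipeline with a KNN
classifier:

```bash
aneufuse simulate --n 32 --seed 7 --out demo
aneufuse run-all --data demo --classifier knn --seed 7 --out demo_out
```

which prints (among the fold-level log lines):

```
wrote cohort manifest: demo/manifest.csv
knn: F2=0.717 ACC=0.656 AUC=0.828
```

`demo_out/features.csv` holds the fused 136-column feature table (25
morphological + 107 radiomics + 2 deep + 2 clinical, group-prefixed names,
plus the rupture label); `demo_out/report.json` holds per-fold and mean
metrics, the hyperparameters chosen per fold, the selected feature subsets
and the mean ROC points. An AUC well above 0.5 means the nested-CV pipeline
recovered the morphological signal planted by the generator (labels follow
a logistic in lesion size and lobulation); at this small n the estimate is
noisy — the package's reference experiment uses 125 cases.

The stages are also available separately (`aneufuse morph`,
`aneufuse radiomics`, `aneufuse extract`, `aneufuse select`,
`aneufuse evaluate`) and as library functions
(`aneufuse.morphometrics.morphological_features`,
`aneufuse.radiomics.extract_radiomics`, `aneufuse.selection.select_features`,
`aneufuse.evaluate.nested_cv`, ...). External cohorts are described by a CSV
manifest with columns `case_id, volume, mask, mesh, sex, age, ruptured`
(NIfTI/MetaImage volumes and masks, binary or ASCII STL meshes).

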