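# lbpradiomics

Texture-based radiomics for two-class brain-MRI classification, built around
four multi-scale, grouped-neighborhood **rotation-invariant uniform local
binary pattern (riu2 LBP)** descriptors. The package covers the full
workflow: NIfTI slice extraction and resizing, LBP histogram features,
recursive-feature-elimination (RFE) selection, and SVM / random-forest
classification with cross-validated and held-out metrics — plus a seeded
phantom-cohort generator so everything is testable without any imaging data.

## The descriptor

For a center pixel *c* and an ordered group of *P* lattice neighbors
*g₁…g_P*, each neighbor contributes a bit *bₖ = 1[I(gₖ) ≥ I(c)]*. With
*U* = number of circular 0↔1 transitions of *(b₁…b_P)*, the riu2 code is

```
code = Σ bₖ   if U ≤ 2        (uniform pattern)
     = P + 1  otherwise        (non-uniform bucket)
```

giving *P* + 2 codes (10 / 18 / 26 for *P* = 8 / 16 / 24) that are invariant
to circular shifts of the neighbor sequence and to any monotone intensity
transform. Instead of a single ring, the window's pixels are partitioned
into groups ("regions") read along a clockwise concentric-ring spiral:

| variant | window | groups × bits | per-slice features | per-subject (5 slices) |
|---------|--------|---------------|--------------------|------------------------|
| I       | 5×5    | 3 × 8         | 30                 | 150                    |
| II      | 7×7    | 6 × 8         | 60                 | 300                    |
| III     | 7×7    | 3 × 16        | 54                 | 270                    |
| IV      | 7×7    | 2 × 24        | 52                 | 260                    |

Each group yields a (*P* + 2)-bin code histogram per slice; histograms are
concatenated over regions and slices into the subject's feature vector.
RFE ranks the features with a linear SVM (or random-forest importances) and
keeps the top ⌈(1 − t)·N⌉ by rank (t = 0.9 keeps 15 of 150); a linear-kernel
SVM or a 150-tree random forest is then trained on a class-balanced 75 %
cohort with 10-fold cross-validation and evaluated on the held-out 25 %
(accuracy, precision, recall, F1, AUC-ROC, confusion matrix; patient =
positive class).

## Worked example

A fully synthetic run — 40 phantom subjects (20 per class), patients carry a
speckle micro-texture blended at weight 0.8 into a 24-px-radius disc:

```bash
lbpradiomics simulate --out cohort --n-per-class 20 --delta 0.8 --seed 7
lbpradiomics extract --manifest cohort/manifest.csv --variant I \
    --slices 0,1,2,3,4 --out features.csv
lbpradiomics train-eval --features features.csv --estimator svm --seed 7 --out run
```

prints

```
Texture radiomics classification
========================================
estimator       : svm (linear kernel)
subjects        : 40 (train 30 / test 10)
features        : 150 -> 15 selected (RFE, score >= 0.9)
train accuracy  : 100.00 %
CV accuracy     : 100.00 % (+/- 0.00, 10-fold)
test accuracy :  80.00 %
precision     : 100.00 %
recall        :  60.00 %
f1-score      :  75.00 %
AUC-ROC       :  0.840
confusion     : TP=3 FN=2 FP=0 TN=5
top features    : s1_g1_c6 (1.000), s3_g2_c6 (0.993), s4_g2_c9 (0.987), ...
```

Reading: the 150 variant-I features (5 slices × 3 regions × 10 codes) were
reduced to 15; the SVM separates the training cohort perfectly, and on the
10 held-out subjects it classifies 8 correctly (3 of 5 patients, all 5
controls). Feature names like `s1_g1_c6` are slice 1, region 1, riu2 code 6
— an edge-type code, as expected for a planted edge-density contrast.

The same objects are available as a library: build a
`TextureRadiomicsModel` from a feature table and call `.fit()` for a results
object with `.summary()`, the RFE `selection`, CV metrics and the test
`report`:

```python
from lbpradiomics import TextureRadiomicsModel
res = TextureRadiomicsModel.from_csv("features.csv", estimator="svm", seed=7).fit()
print(res.summary())
```

Real cohorts plug in through the same manifest CSV (`subject_id, path,
modality, label` pointing at `.nii`/`.nii.gz` files); for ~205-slice
T1-weighted volumes the default slice window (indices 100–140, step 10)
applies and slices are resized to 180×180.

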