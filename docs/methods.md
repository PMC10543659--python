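# Methods

## Grouped-neighborhood riu2 LBP

Classic LBP thresholds the neighbors of a pixel against the pixel itself and
encodes the bits; the rotation-invariant uniform (riu2) mapping collapses
each circular pattern to its number of set bits when it has at most two
circular 0↔1 transitions, and to a single non-uniform bucket otherwise,
giving P + 2 codes for P bits. The descriptors here extend this to square
lattice windows (5×5 and 7×7) whose 24 or 48 non-center pixels are
partitioned into equal groups; each group is coded independently, so one
variant produces several code images per slice at slightly different spatial
scales and sampling densities.

**Pixel-to-group assignment.** The window's pixels are ordered along one
clockwise concentric-ring spiral: ring 1 (Chebyshev radius 1, 8 pixels),
then ring 2 (16), then ring 3 (24), each ring traversed clockwise from its
top-left corner. Groups are consecutive chunks of that spiral: variant I
(5×5) cuts the 24-pixel spiral into 3×8, variant II (7×7) into 6×8, variant
III into 3×16, variant IV into 2×24. This rule is deterministic, satisfies
all the group-count and window constraints, and keeps each group spatially
coherent (consecutive offsets within a ring are lattice neighbors), but it
is one defensible choice among several — the historical assignment for these
variants is not fully specified anywhere machine-readable, so the grouping
is exposed as a plain data object (`GroupedNeighborhood`) that can be
swapped without touching the coder. Groups that span a ring boundary are
arcs rather than closed circuits; after the riu2 mapping the starting point
of the traversal is immaterial within a rotation class.

**Conventions.** Neighbor ≥ center ⇒ bit 1 (ties count as 1). Codes are
computed only where the full window fits (a margin of (side−1)/2 pixels is
dropped; no padding, so no fabricated intensities at image borders). Any NaN
inside the *full* window invalidates that center: its cell is masked and
excluded from histograms, with the masked count reported. Intensities are
compared as-is; riu2 codes depend only on intensity order, so no scaling is
applied before coding.

## Features

Each code image is tallied into an exact (P + 2)-bin histogram over the
valid centers; a slice's region histograms are concatenated in region order,
and a subject's slice vectors in slice order, giving 150/300/270/260
features for variants I–IV at five slices. Raw counts are kept (all slices
are resized to a fixed 180×180, so counts are comparable across subjects); a
`normalize` option divides each region's histogram by its valid-center count
for variable-size use. Feature names encode provenance as
`s{slice}_g{region}_c{code}` and parse back losslessly.

## Preprocessing

NIfTI volumes are read with nibabel and the in-plane matrix transposed so
slices index the third axis; 4-D resting-state volumes are collapsed over
time by taking the first time point (default) or the mean. The default
analysis window takes slice indices 100–150 in steps of 10; that arithmetic
yields six indices while five slices per subject are used, so the committed
default is the first five (100…140), overridable by an explicit index list.
Short volumes (e.g. 27-slice resting scans) reject the default window with a
configuration error rather than guessing. Kept slices are resized
bilinearly to 180×180; an optional strict rule drops slices whose *native*
in-plane size is below 180×180 (boundary inclusive: exactly 180 is kept).
Slice indices are 0-based throughout.

## Selection and classification

The cohort is split by a class-balanced holdout: the training set draws
`round((1 − test_fraction)·n) // 2` subjects per class (seeded, without
replacement) and everything else is the test set — with 72 subjects (39/33)
and a 0.25 fraction this gives train 54 (27+27) and test 18 (12+6).

RFE eliminates one feature per step using linear-SVM coefficient magnitudes
(features standardized first; linear SVMs are scale-sensitive) or
random-forest impurity importances, yielding a full ranking. The reported
importance score is `(N − rank + 1)/N` — 1.0 for the best feature. A
threshold `t` is applied as a top-fraction rule keeping the `ceil((1−t)·N)`
best-ranked features (15 of 150 at t = 0.9); every selected feature has
score ≥ t, and when `(1−t)·N` is an integer the next-ranked feature sits
exactly on the score boundary without being selected — the count rule is the
binding definition. Ties everywhere break by original column order.

Classifiers are fixed, not tuned: `SVC(kernel="linear", gamma="auto")`
behind a train-fitted standardizer, and `RandomForestClassifier` with 150
trees (seeded); no hyperparameter search. Cross-validation is stratified
k-fold (k = 10 default, shuffled, seeded) on the training cohort; when k
exceeds the smallest class (e.g. leave-one-out) plain shuffled folds are
used. Test metrics treat the patient class as positive; accuracy,
precision, recall and F1 come from the confusion matrix with zero
denominators mapped to 0.0, and AUC-ROC uses the rank statistic over
continuous scores (SVM margin, or RF patient-class probability) with the
midrank convention for ties, so all-tied scores give 0.5.

## Phantom cohorts

The generator emulates the *statistical* situation of a small MRI radiomics
study — two classes whose difference is a localized micro-texture — not
anatomy or MR physics. A slice is a smooth random field (Gaussian blur
σ = 6 px, intensity range ≈ 30–220) inside an ellipse on a dark background,
plus additive Gaussian noise (SD 2). For patients, a binary speckle texture
(values 40/200) is alpha-blended at weight δ ∈ [0,1] inside a disc (default
radius 24 px at side 180, centered). Speckle raises local edge density,
which shows up in the mid-range riu2 codes of the 8-bit groups. Randomness
derives from one root seed via `SeedSequence([seed, class, subject, slice])`,
so cohorts are bit-reproducible; δ = 0 makes the classes exchangeable in
distribution.

The noise SD and lesion radius were set so that δ is the operative dial of
the generator: at SD 2 / radius 24 the variant-I pipeline's mean test
accuracy over seeds rises from chance at δ = 0 through ≈ 0.75–0.95 at
δ = 0.3–0.6 to 1.0 at δ = 0.9 (40 subjects). Larger noise makes the LBP
response of the *whole* image noise-dominated and buries a small planted
focus — a real failure mode of texture radiomics worth remembering when
interpreting the phantom results. What passing phantom tests shows is that
the chain (coding → histograms → selection → classifier) transmits a genuine
localized texture contrast and transmits nothing when there is none; it says
nothing about effect sizes, registration, scanner effects or anatomy in real
cohorts.

## Problem sizes used in the automated checks

Alphabet and invariance checks enumerate all 2⁸ and 2¹⁶ patterns exhaustively
and sample 10⁶ random 24-bit patterns (the P = 24 alphabet is additionally
constructed analytically: one single-run pattern per popcount plus the
non-uniform bucket). Coder-vs-oracle equivalence uses 50 random 20×20
images across all variants and groups against a naive per-pixel double-loop
reference. The end-to-end power curve uses 40-subject cohorts at
δ ∈ {0, 0.3, 0.6, 0.9} with 5 seeds each, and the null (δ = 0) chance check
20 seeded repeats, i.e. 200 held-out predictions.

## Known limitations

- The grouping rule is a committed stand-in (see above); alternative
  assignments plug in via `GroupedNeighborhood` but are not shipped.
- Headline accuracies from any real cohort depend on manual slice curation
  and site effects; the package reproduces the machinery and its arithmetic,
  not external-data results.
- Binary classification only; no calibration, no hyperparameter search, no
  registration/skull-stripping (out of scope by design).
- Train/validation accuracy gaps of small cohorts are reported, never
  asserted — with ~30 training subjects and 150 candidate features,
  selection bias makes training and even CV scores optimistic, which the
  phantom null check makes visible.
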