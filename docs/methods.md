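# Methods

## Geometric model

A face is 22 named anatomical landmarks with 3D coordinates (X
rightward, Y upward, Z toward the camera; millimetres for capture
data, though no result depends on the unit). Two primitive features
are defined on landmark tuples:

* **distance** d(p₁, p₂) = ‖p₁ − p₂‖, divided by the inner-eye-corner
  separation d(p₈, p₉); this single 3D normalizer is applied to both
  3D and 2D distances, making every distance feature dimensionless
  and identical across uniformly scaled faces. The inner-eye-corner
  separation is used because it is stable under expression: none of
  the six basic expressions moves the eye corners appreciably.
* **angle** A = arccos[(p₃ − p₂)·(p₁ − p₂)/(‖p₃ − p₂‖‖p₁ − p₂‖)] at
  vertex p₂, in radians. Angles are intrinsically scale-free and are
  not normalized. The cosine is clamped to [−1, 1] before the arccos
  so that round-off on (anti)parallel arms cannot produce NaN; a
  zero-length arm raises an error naming the degenerate pair and the
  descriptor.

2D variants drop the Z coordinate — a frontal-pose assumption; no
registration or reprojection is attempted. Consequently 3D features
are invariant to any global similarity transform (verified to 1e−9 in
tests), while 2D features are invariant only to in-plane similarities
and deliberately sensitive to out-of-plane rotation (both directions
are asserted).

The 89-descriptor catalog (19 3D distances, 27 3D angles, 23 2D
distances, 20 2D angles, in that fixed column order) is stored as a
data file, `data/feature_catalog.csv`, not as code: a transcription
error surfaces as a failed count/arity test rather than a silently
redefined feature. The 47-descriptor subset found by the best
genetic-algorithm fit ships the same way (`data/ga_selected_ids.txt`)
and reduces the group counts 27→14, 19→12, 20→8, 23→13 (48.15%,
36.84%, 60%, 43.48%; 47.19% overall).

## Landmark dialects

The Bosphorus-style reader maps file landmark names to canonical
indices through an editable table; of the 24 points in such files the
two ear-lobe points are excluded — the mapping file marks them index
0, and users can remap any name. The 51-point avatar scheme is
adapted by a versioned table: 19 canonical points are direct copies
and three have no correspondent — the two nose-saddle points
(midpoint of inner brow and inner eye corner on each side) and the
outer middle of the upper lip (midpoint of the two Cupid's-bow
peaks). Which points to interpolate, and from which donors, is a
design choice of this package; because every target is a copy or
midpoint, the adaptation commutes exactly with global similarity
transforms, which the tests exploit.

The generic long-form CSV keys records by (subject_id, expression,
landmark_index): one subject legitimately contributes several
expressions, so duplicates are detected on the full triple. Floats
are written with `repr` and parsed in round-trip mode, making
write∘read the identity bit for bit.

## PCA selection

Mean-centred (never variance-standardized) covariance PCA via SVD of
the centred data matrix. Given a variance fraction v ∈ (0, 1], the
minimal k is retained with (Σᵢ₌₁ᵏ λᵢ)/(Σλ) ≥ v − 1e−12; the epsilon
absorbs round-off when the threshold is exactly attainable (v = 1 on
rank-r data yields k = r). The "selected features" are the component
scores, not a subset of original columns; tests verify k and the
spectrum against an explicit eigendecomposition of the covariance
matrix to 1e−8.

## Wrapper genetic algorithm

Individuals are 89-bit masks. Fitness is the mean accuracy (%) of a
cubic-kernel SVM, K(x, y) = (1 + x·y)³ with C = 1, under stratified
10-fold CV on the masked columns; folds are frozen per run (one
`cv_seed`) so fitness is a deterministic function of the mask and
selection pressure acts on the subset, not on resampling noise. The
generational loop: 10 tournaments per generation, each drawing 5
distinct individuals without replacement and taking the best two as
parents; one-point crossover at a uniform cut in [1, 88]; per-gene
bit-flip mutation at rate 1/89 (the canonical choice for "simple"
mutation; configurable); the all-time best individual then replaces
the worst offspring, keeping the population at 20 and making the
best-fitness history nondecreasing by construction. An all-zero mask
scores 0 rather than being repaired, so it can never become elite.
Identical data, configuration and seeds give bit-identical results.

Numerical choices in the fitness evaluator: the polynomial Gram
matrix is computed once per mask and sliced per fold (cheaper than
re-deriving the kernel inside each fold); the SVM solver tolerance is
0.1 rather than the library default 1e−3, because fitness only has to
*rank* masks and the ranking is stable far before full dual
convergence; and features enter the kernel unstandardized — the
geometric features are already dimensionless and O(1). The reporting
path (below) is stricter. Fitness values are cached by mask bytes,
which saves roughly a quarter of evaluations in a converging run.

The repeat-30-runs protocol (report best/worst fits) is a seeded loop
in the CLI (`replicate-ga30`), not an algorithm change.

## Classifiers and evaluation protocol

SVMs use the exact kernel (1 + x·y)^d (gamma = 1, coef0 = 1 in the
library parameterization), C = 1, one-vs-one over the 15 class pairs
with majority vote. Labels are encoded as integers in the fixed
display order SU, SA, HA, FE, DI, AN before fitting, so vote ties
resolve to the lowest index in that order. k-NN uses k = 1 with
Euclidean distance. The subspace ensemble is 200 1-NN learners, each
on round(d/2) features drawn without replacement, combined by
averaging per-class scores (a bagging classifier with bootstrap
disabled is exactly this algorithm). In the evaluation path features
are standardized per training fold (statistics learned on the train
split only).

`evaluate` runs n independent stratified 10-fold CVs (default n = 10,
configurable — the summary statistics std/median/mean/max/min are
taken over the n per-repetition mean accuracies; a fold-level
interpretation would conflate fold noise with repetition spread).
Fold predictions are pooled into one confusion matrix, row-normalized
to percent; matrices are displayed rounded to integers but stored at
full precision.

SMOTE balances each class to an explicit per-class target before
CV — matching the protocol this package follows, where balancing
precedes the experiments; the methodologically stricter,
leakage-free variant (balance the training split of every fold) is
available as `evaluate(..., smote_within_folds=target)` but is not
the default and yields different absolute numbers. k = 5
neighbours by default; a class with a single member is an error, and
a class above the target is an error (SMOTE only oversamples).

## Synthetic faces

The generator emulates a frontal 3D-landmark capture of posed
expressions. A fixed bilaterally symmetric neutral template
(inner-eye-corner separation 34 mm) is deformed by per-expression
displacement fields whose *directions* encode the standard
qualitative descriptions (surprise: brows up, jaw open; anger: inner
brows down and together, lips pressed; disgust: upper lip raised and
curled, deliberately left/right asymmetric; fear: brows raised and
pulled together, mouth stretched; happiness: corners pulled back
toward the ears, mouth open; sadness: inner brows bent up, corners
drooped). Displacement *magnitudes* are free parameters of this
package. Nuisance model: expression intensity ~ U(0.6, 1.4);
per-face identity jitter N(0, 1.5 mm) per coordinate; capture noise
N(0, 1.5 mm); a random global similarity (rotation up to ±10°/±10°/
±15° about X/Y/Z, scale U(0.9, 1.1), translation ±25 mm).

These defaults were fixed once so that the default design (104 faces
per class) puts cubic-SVM 10-fold accuracy in the low 90s with the
full catalog and within a few points of that with the 47-feature
mask — separable classes with realistic confusion structure. What
passing tests show is therefore that the *pipeline* behaves correctly
on data with this geometry; they say nothing about accuracy on real
capture databases, whose identity variation (non-rigid shape
differences, annotation error structure) is richer than jitter plus a
similarity transform.

Planted-signal data for selection-recovery experiments is generated
directly in feature space (10 informative columns among 89, class
mean shifts of norm 4 on unit-variance noise): the geometric
descriptors share landmarks too heavily for a landmark-level
construction to make "exactly 10 informative features" well defined.
The strength-4 default leaves each planted column with several
accuracy points of marginal value (accuracy is not saturated), which
is the property a recovery experiment needs.

## Problem sizes in the shipped tests

The acceptance tests run the recovery experiment at 60 faces per
class with a reduced GA (population 20, 60 generations, 20 seeded
runs), the end-to-end regime check at 104 faces per class with 10
repetitions of 10-fold CV, and the remaining suites on small
constructed fixtures; these sizes keep the whole suite comfortably
reproducible on a single CPU while leaving every statistical
assertion (recovery rate, accuracy bounds, chance-level checks) with
clear margin.

## Known limitations

* No face/landmark detection, registration, occlusion or pose
  handling: landmarks are taken as given, frontal.
* The 2D features assume the frontal pose; out-of-plane rotation is a
  modelled nuisance, not corrected.
* Appearance features (texture, wrinkles), temporal dynamics and
  deep-feature baselines are out of scope.
* The excluded-landmark pair of 24-point files and the three
  interpolated avatar points are documented package defaults, editable
  via the data tables, not facts about any upstream database.
* Reported accuracies on synthetic data characterize the generator's
  regime, not any real database.
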