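# geomexpr

Landmark-based geometric recognition of the six basic facial
expressions — anger (AN), disgust (DI), fear (FE), happiness (HA),
sadness (SA) and surprise (SU) — for researchers working with 3D
facial landmark data (manually annotated scans or virtual-avatar
exports) rather than raw images.

The pipeline has four stages:

1. **Feature extraction.** From 22 anatomical landmarks
   (eyebrows, eye corners, nose, lips, chin) with coordinates
   p ∈ ℝ³, a fixed catalog of 89 geometric descriptors is computed:
   distances d(p₁, p₂) = ‖p₁ − p₂‖, each divided by the
   inner-eye-corner separation d(p₈, p₉) so they are scale-free, and
   angles A = arccos[(p₃ − p₂)·(p₁ − p₂) / ‖p₃ − p₂‖‖p₁ − p₂‖] at
   vertex p₂ — 27 angles and 19 distances in 3D, and 20 angles and
   23 distances on the frontal X-Y projection (2D).
2. **Class balancing.** SMOTE oversampling to a common per-class
   count (synthetic rows x + u·(x_nn − x), u ~ U(0,1), x_nn a
   same-class nearest neighbour).
3. **Feature selection.** Either PCA variance thresholding (retain
   the minimal leading components reaching 97/98/99% cumulative
   variance) or a wrapper genetic algorithm over 89-bit masks whose
   fitness is the stratified 10-fold CV accuracy of a cubic-kernel
   SVM on the masked features (population 20, tournament best-2-of-5,
   one-point crossover, bit-flip mutation at 1/89, elitism). The
   best published GA fit — 47 of 89 features — ships as a constant
   (`ga_selected_mask()`), cutting the catalog by 47.2% while keeping
   the 3D/2D mix that carries the expression signal.
4. **Classification.** One-vs-one polynomial-kernel SVMs
   K(x, y) = (1 + x·y)^d with d ∈ {2, 3}, 1-nearest-neighbour, or a
   random-subspace ensemble of 200 1-NN learners on round(d/2)
   features each; evaluated by repeated stratified 10-fold CV with
   summary statistics and a row-normalized confusion matrix in the
   fixed order SU, SA, HA, FE, DI, AN.

Because the licensed landmark databases cannot be redistributed, the
package includes a synthetic face generator: a neutral 22-landmark
template deformed by per-expression displacement fields (surprise
raises the brows and opens the jaw, anger knits the brows and presses
the lips, ...) plus identity jitter, capture noise and a random
similarity transform. Every stage is therefore testable end to end
with no downloads.

## Worked example

```python
import geomexpr as gx

faces = gx.generate_dataset(gx.SyntheticConfig(n_per_class=40, rng_seed=1))
fm = gx.extract_matrix(faces)          # 240 x 89 feature matrix
report = gx.evaluate(gx.SVM3, fm.X, fm.y, n_repetitions=5, seed=2)
print(report.summary().round(2))
```

prints

```
Standard deviation     0.78
Median accuracy       87.50
Mean accuracy         87.92
Maximum accuracy      88.75
Minimum accuracy      87.08
```

i.e. the cubic SVM separates the six synthetic expression classes at
~88% mean accuracy over five independent 10-fold cross-validations,
with sub-point spread between repetitions. `report.confusion_frame()`
shows the per-class structure (fear/surprise confusions dominate, as
both raise the eyebrows). The `examples/` directory contains one
short script per capability: feature extraction, classification, PCA
selection, GA selection with a planted informative subset, and a full
deterministic pipeline run.

A thin CLI mirrors the library:

```bash
geomexpr simulate --n-per-class 104 --seed 1 --out faces.csv
geomexpr extract --in faces.csv --out features.csv
geomexpr select-ga --features features.csv --pop 20 --gens 250 --seed 1 --out mask.json
geomexpr evaluate --features features.csv --mask ga47 --classifier svm3 \
    --reps 10 --seed 1 --report report.json
geomexpr reduction-report
```

## Landmark file formats

* **Bosphorus-style text**: optional `#` comments, a point count,
  then alternating name / `x y z` lines. Names map onto the
  canonical 22-point scheme via `src/geomexpr/data/bosphorus_names.csv`
  (ear-lobe points of 24-point files are ignored). Example:

  ```
  # Landmark file
  22
  Outer left eyebrow
  -55.0 42.0 -10.0
  Middle left eyebrow
  -35.0 50.0 0.0
  ...
  ```

* **Generic long-form CSV/JSON**: columns `subject_id, expression,
  landmark_index, x, y, z`; lossless round-trip; emitted by the
  simulator.
* **51-point avatar lists**: adapted to the 22-point scheme by
  `adapt_uibvfed` using a versioned mapping table (19 direct copies,
  3 midpoint interpolations).

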