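"""Classify the six basic expressions on synthetic faces.

Generates a balanced labelled dataset, extracts features, and runs
the repeated stratified 10-fold protocol with the cubic-kernel SVM,
printing the summary statistics and the row-normalized confusion
matrix (percent, class order SU SA HA FE DI AN).
"""

import geomexpr as gx

cfg = gx.SyntheticConfig(n_per_class=40, rng_seed=1)
faces = gx.generate_dataset(cfg)
fm = gx.extract_matrix(faces)
print(f"dataset: {fm.X.shape[0]} faces x {fm.X.shape[1]} features")

report = gx.evaluate(gx.SVM3, fm.X, fm.y, n_repetitions=5, seed=2)
print("\ncubic-SVM, 5 x 10-fold CV")
print(report.summary().round(2).to_string())
print("\nconfusion matrix (% of true class):")
print(report.confusion_frame(as_int=True).to_string())
print(
    "\nEach row is a true expression; diagonal entries are per-class "
    "accuracies. Geometrically similar pairs (e.g. fear/surprise both "
    "raise the brows) account for most off-diagonal mass."
)
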