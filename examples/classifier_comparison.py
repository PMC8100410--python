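"""Compare the five baseline classifiers on a PCA-reduced synthetic cohort.

Runs the tabular half of the pipeline: generate a labelled cohort,
split 80/20 with stratification, reduce dimensionality to 98% retained
variance, then train and evaluate each baseline.  Accuracy is the
confusion-matrix trace over the test count; macro AUC averages the
one-vs-rest areas across the four classes.
"""

from adseverity import classify, evaluate, reduction
from adseverity.synthetic import make_cohort

cohort = make_cohort(n_patients=1000, effect_size=3.0, seed=1)
sp = classify.split(cohort.features, cohort.classes, classify.SplitSpec(seed=1))

spectrum = reduction.pca_fit(sp.X_train)
result = reduction.select_components(spectrum, sp.X_train, variance_threshold=0.98)
X_test = reduction.transform(spectrum, sp.X_test, result.n_selected)
print(f"PCA kept {result.n_selected} of 285 features "
      f"({reduction.reduction_percent(285, result.n_selected)}% reduction, "
      f"{100 * result.ncse_at_selection:.1f}% variance)")

print(f"{'method':<8}{'accuracy %':>11}{'macro AUC':>11}")
for method in classify.METHODS:
    model = classify.train(method, result.reduced_table, sp.y_train, seed=1)
    pred, scores = classify.predict(model, X_test, return_scores=True)
    rep = evaluate.evaluation_report(sp.y_test, pred, scores)
    print(f"{method:<8}{rep['accuracy_pct']:>11}{rep['macro_auc']:>11}")
print("(200 held-out patients; higher is better on both columns)")
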