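"""Train the 1-D CNN severity classifier and report its confusion matrix.

Same pipeline front end as the baselines (cohort -> 80/20 split -> PCA
at 98% variance), then 420 iterations of mini-batch SGD on the small
convolutional network.  The confusion matrix rows are the true classes
(low, mild, moderate, severe); the diagonal holds correct diagnoses.
"""

import numpy as np

from adseverity import classify, cnn, evaluate, reduction
from adseverity.synthetic import make_cohort

cohort = make_cohort(n_patients=1000, effect_size=3.0, seed=0)
sp = classify.split(cohort.features, cohort.classes, classify.SplitSpec(seed=0))
spectrum = reduction.pca_fit(sp.X_train)
result = reduction.select_components(spectrum, sp.X_train, 0.98)
X_test = reduction.transform(spectrum, sp.X_test, result.n_selected)

arch = cnn.build(result.n_selected)
print(f"architecture: conv(16x5) -> FC {arch.fc_sizes} -> {arch.n_classes} classes "
      f"({arch.n_parameters:,} parameters)")
model, trace = cnn.train_cnn(arch, result.reduced_table, sp.y_train,
                             cnn.TrainingConfig(iterations=420, seed=0))
print(f"final training loss {trace['loss'][-1]:.3f}, "
      f"batch accuracy {trace['accuracy'][-1]:.2f}")

pred, probs = cnn.predict_cnn(model, X_test)
rep = evaluate.evaluation_report(sp.y_test, pred, probs)
print("test confusion matrix (rows = true class):")
print(np.array(rep["confusion_matrix"]))
print(f"test accuracy {rep['accuracy_pct']}%, macro AUC {rep['macro_auc']}")
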