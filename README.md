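# adseverity

Staging the severity of Alzheimer's disease from imaging-derived
morphometric features. The package implements, as a tested end-to-end
pipeline, the analysis chain used in feature-based dementia-severity
studies: volumetric denoising, robust multitask feature learning, PCA
dimensionality reduction, Mini-Mental State Examination (MMSE) severity
labelling, and multi-classifier severity prediction with
confusion-matrix and ROC reporting. It is written for methodologists
who want to exercise and probe this pipeline without access to
restricted clinical imaging data: every input can be generated
synthetically with known ground truth.

## The methods at its core

**Variational denoising.** A volume `I` observed as a noisy `I0` is
restored by minimising

```
E(I) = Σ_Ω [ 1 + β² |∇I|² ] + (λ/2) Σ_Ω (I − I0)²
```

with forward-difference gradients and zero-flux boundaries, by monotone
explicit gradient descent. A stochastic local search proposes classical
filter candidates (Gaussian blur with a 3- or 5-voxel kernel, mean
filter, global intensity rescaling in [0.7, 1.3]) and accepts one only
when it lowers `E`. Quality is scored by PSNR = 10·log₁₀(255²/MSE).

**Robust multitask feature learning (rMTFL).** Given m regression
tasks {(Xᵢ, yᵢ)} over d shared features (here: the six MMSE follow-up
time points as tasks), the weight matrix is decomposed W = P + Q and
estimated by

```
min_{P,Q} Σᵢ (1/(m·nᵢ)) ‖Xᵢᵀ(pᵢ+qᵢ) − yᵢ‖² + λ₁‖P‖₁,₂ + λ₂‖Qᵀ‖₁,₂
```

where `‖·‖₁,₂` sums row Euclidean norms. Row-sparse P carries the
features shared across tasks; column-sparse Q absorbs whole outlier
tasks. The solver is a monotone proximal-gradient method (backtracking
ISTA) with group soft-thresholding `g → g·max(0, 1 − t/‖g‖₂)`.

**PCA with the cumulative-eigenvalue rule.** Components are kept in
descending eigenvalue order; the normalized cumulative sum of
eigenvalues, NCSE(i) = Σ_{n≤i} λₙ / Σ_{n≤N_f} λₙ, selects the smallest
i reaching a 98% variance threshold (167 of 285 features in the
original study, a 41.4% reduction).

**Severity prediction.** MMSE scores (integers 0–30) are staged as
low 25–30, mild 20–25, moderate 10–20, severe 0–10. Five baselines
(KNN, RBF-SVM, decision tree, LDA, random forest) and a small 1-D CNN
(16 length-5 convolutions → ReLU → fully connected 384/384/384/4 →
softmax, cross-entropy, 420 SGD iterations) are trained on an 80/20
stratified split and reported via per-class sensitivity/precision,
overall accuracy and one-vs-rest ROC/AUC.

## Worked example

```
$ python examples/multitask_feature_learning.py
chosen penalties     : lambda1=0.001, lambda2=0.003 (hold-out MSE 0.0268)
planted support      : [4, 21, 31, 36, 49]
top-5 feature scores : [4, 21, 31, 36, 49]  (match)
planted outlier task : [0]
detected outlier task: [0]  (match)
solver iterations    : 499 (objective non-increasing throughout)
```

Five regression tasks were generated with signal in only 5 of 50
features and one deliberately corrupted task. After penalty selection
by task-wise hold-out, the five largest row norms of P point exactly at
the planted features, and the dominant column of Q flags the planted
outlier task. The other examples cover denoising (`denoise_phantom.py`,
printing a +9.5 dB PSNR gain on a σ=15 phantom), MMSE staging,
baseline-classifier comparison, and CNN training
(`cnn_severity.py`, printing a 97.0% test accuracy confusion matrix).

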