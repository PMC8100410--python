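# Methods

This note records the models implemented in `adseverity`, the defaults
and numerical choices behind them, what the synthetic generators do and
do not emulate, and the known limitations.

## Denoising model

The denoiser minimises, over a 3-D volume `I` with noisy observation
`I0` on the 0–255 intensity scale,

    E(I) = Σ_Ω [ 1 + β²|∇I|² ] + (λ/2) Σ_Ω (I − I0)²,

i.e. a first-order smoothness term balanced against quadratic fidelity,
plus a constant voxel-count term kept so that a constant field of N
voxels has energy exactly N. Gradients are forward finite differences
with zero-flux (replicate) boundary conditions — the standard
variational discretisation; the energy gradient uses the exact adjoint
(backward-difference divergence), verified against central differences
in the tests.

Minimisation is explicit gradient descent made monotone by step
backtracking (halve until the energy does not increase, re-grow by 1.2
after success). With probability `local_search_rate` per iteration a
candidate local search generates one volume per configured filter
operation — Gaussian blur with a kernel drawn from {3, 5} voxels, a
mean filter of the same sizes, or a global intensity rescale drawn from
[0.7, 1.3] — and adopts the minimum-energy candidate only if it beats
the current iterate, so the energy trace is non-increasing end to end.

Defaults: β = 0.5, λ = 0.5, step 0.2, 100 iterations, local-search
rate 0.2. β and λ were fixed by a small scan over σ = 15 phantoms
during development: the implied smoothing length √(2β²/λ) = 1 voxel
removes most high-frequency noise without blurring blob-scale
structure, giving roughly +8 dB mean PSNR over the noisy input.
Substantially smaller λ/β ratios over-smooth and can *lose* PSNR. An
optional geometric schedule of β and λ over iterations exists but is
disabled by default, since no principled schedule shape presents
itself. PSNR is computed against the clean phantom when one exists,
otherwise against the pre-denoising input; identical volumes report
+∞. 4-D series are denoised volume by volume.

## Robust multitask feature learning

The estimator solves

    min_{P,Q} Σ_{i=1}^m (1/(m·n_i)) ‖X_iᵀ(p_i+q_i) − y_i‖² + λ₁‖P‖₁,₂ + λ₂‖Qᵀ‖₁,₂,

with ‖M‖₁,₂ the sum of row Euclidean norms: rows of P group each
feature across tasks (shared structure), rows of Qᵀ — columns of Q —
group each task (outlier structure). The loss is taken at face value
with no extra 1/2, so its gradient carries a factor 2/(m·n_i).
Features are first normalised within each task so every feature row of
X_i has unit norm; all-zero rows are left untouched and reported.

Solver: joint proximal gradient (ISTA) on (P, Q) — both blocks share
the smooth-loss gradient — with group soft-thresholding
g → g·max(0, 1 − t/‖g‖₂) applied to P's rows (threshold step·λ₁) and
Q's columns (step·λ₂). Backtracking enforces the sufficient-decrease
condition, which guarantees a non-increasing objective; acceleration is
deliberately omitted because momentum methods are not monotone.
Initialisation at P = Q = 0; stop at relative objective change below
1e−9 or the iteration cap.

Penalty selection uses a logarithmic grid with task-wise hold-out
validation MSE. Prediction error alone cannot identify the P/Q split —
with weak penalties either component can absorb the other's signal —
so outlier detection supports a relative criterion: task i is flagged
when ‖q_i‖ > 0.8·‖w_i‖, i.e. when the outlier component dominates that
task's weights. On the 20-seed benchmark family (d = 50, m = 5,
n = 100, 5 shared features, 1 outlier task, noise 0.1), fitted outlier
tasks show ratios ≥ 0.88 and clean tasks ≤ 0.69, so the threshold sits
in a wide margin; both support and outlier recovery are exact on all
20 seeds. Feature relevance is the row norm of P; `select_features`
takes the k largest scores with ties broken toward smaller indices.

In the severity pipeline the m = 6 tasks are the MMSE follow-up time
points (months 6–48). How the learned scores feed the downstream
feature table is an open design point: the default keeps all features
and lets PCA reduce, with score-based selection available as a knob.

## PCA and the cumulative-eigenvalue rule

PCA is computed by SVD of the mean-centered training data (unbiased
n−1 normalisation); eigenvalues below 1e−10 are clipped to exactly
zero to stabilise the ratio near rank deficiency, and the final
cumulative value is pinned to 1. The selection rule keeps the smallest
i with NCSE(i) = Σ_{n≤i}λₙ/Σλₙ ≥ 0.98. PCA is fit on the training
split only and applied to the test split; fitting on pooled data would
leak test information into the representation. Covariance (not
correlation) PCA is used because upstream features are already
normalised.

## MMSE staging

Integer scores 0–30 map to four ordinal classes. The published bands
overlap at 25, 20 and 10; the default convention assigns each shared
boundary to the less impaired class (low [25,30], mild [20,25),
moderate [10,20), severe [0,10)), consistent with clinical usage that
treats 25 as within the low band; the opposite convention is available
via an argument. The staging is total, disjoint and monotone, which
the tests assert over all 31 scores. Which follow-up time point
defines a patient's label is not modelled; the synthetic cohort has a
single score per patient.

## Classifiers

The five baselines use scikit-learn with fixed, logged defaults — KNN
k = 5 Euclidean; SVM RBF kernel, C = 1, with probability estimates
enabled so every method exposes per-class scores for ROC; decision
tree Gini, unlimited depth; LDA with automatic shrinkage of the
covariance ("lsqr" solver); random forest with 100 trees. The split is
80/20, stratified, seeded. No hyperparameter search is performed by
default; accuracies on synthetic cohorts are not comparable to any
clinical figure.

The CNN treats the reduced feature vector as a length-L 1-D signal:
16 convolutional filters of length 5, stride 1, symmetric zero
padding (the only geometry consistent with a width-1 input, where a
5×5 kernel collapses to length 5), ReLU, then fully connected layers
384/384/384/4 — following the four-layer enumeration; a 384/384/4
variant is available through `fc_sizes=(384, 384)` — and a softmax
with cross-entropy (probability floor 1e−12). The network is plain
NumPy with hand-written backpropagation, verified against central
finite differences. Training runs 420 optimizer steps (steps, not
epochs) of mini-batch SGD, batch 32. The default optimizer is
heavy-ball SGD with learning rate 1e−3 and momentum 0.9: plain SGD at
this rate does not converge within the fixed 420-step budget on the
reference cohort, while momentum reaches ≥ 0.96 test accuracy across
seeds. Inputs are z-scored with training-set statistics (stored in the
model and reapplied at prediction). Initialisation is He-style
symmetric Gaussian, biases zero; batching and initialisation are fully
seeded, so training is bit-reproducible. No dropout or weight decay is
applied.

## Evaluation

Confusion matrices are 4×4 with rows = true class in the fixed order
(low, mild, moderate, severe). Sensitivity is the diagonal over the
row sum, precision over the column sum; a class with no true (or
predicted) members yields an undefined entry reported as "n/a", never
0. Accuracy is the trace over the total and equals the
frequency-weighted mean of sensitivities (asserted to 1e−12).
One-vs-rest ROC curves come from scikit-learn's threshold sweep (equal
scores collapse into one step) with trapezoidal AUC, cross-checked in
the tests against the brute-force Mann–Whitney concordance statistic.
Percentages are reported to one decimal. A macro-averaged AUC is also
reported.

## Synthetic data: what it emulates, and what it does not

* **Phantoms** emulate only the geometry of the volumetric denoising
  problem: 3-D grids on a 0–255 scale with smooth ellipsoidal blobs
  (background 60, amplitudes 60–160, so σ = 15 noise stays essentially
  unclipped) and additive Gaussian noise; Rician noise is an option.
  They contain no anatomy, BOLD dynamics or scanner artifacts, so
  PSNR gains here demonstrate the optimiser works, not that it matches
  any clinical denoising figure.
* **Multitask problems** plant exactly the structure the estimator
  assumes (row-sparse P, column-sparse Q, Gaussian designs and noise).
  Recovery results certify the solver and selection machinery, not
  robustness to model misspecification.
* **Cohorts** draw features as class-conditional Gaussians with unit
  within-class SD and class means i.i.d. N(0, effect_size²) per
  feature, so `effect_size` is the per-feature dispersion of class
  means in SD units and 0 collapses all classes. Default composition
  is 1000 patients at proportions (0.69, 0.21, 0.092, 0.008) —
  low-dominant with a small severe class, mirroring the published
  cohort's composition — with MMSE scores drawn uniformly (integers)
  inside each generating class's band. Default effect size 3 makes the
  cohort strongly separable: classifier accuracies near 100% on it say
  the pipeline is wired correctly, nothing about clinical accuracy.

All generators are bit-reproducible from their seed.

## Problem sizes

Routine verification uses 32×32×16 phantoms (10 seeds), d = 50 / m = 5
multitask problems (20 seeds), and 1000-patient cohorts (285 features),
chosen so the entire suite and the acceptance script each complete in a
few minutes on one CPU while exercising every code path at
non-trivial scale.

## Known limitations

* The published clinical accuracies (e.g. CNN 96.7% on the restricted
  cohort) are not reproducible without the original data and are not
  targets of this package; the two recomputable published numbers (the
  41.4% feature reduction and the 95.1% low-class sensitivity implied
  by the 656/690 confusion row) are checked exactly.
* The original text reports both 94.1% and 95.1% for the same 656/690
  row; 656/690 = 95.07%, so 95.1% is taken as the consistent value.
* Eq.-level admissibility conditions of the wavelet-style transform
  behind the denoiser's naming have no computable role and are not
  implemented; the denoiser is the energy minimisation plus candidate
  search described above.
* λ₁/λ₂ selection by prediction error cannot identify the P/Q
  decomposition; the relative outlier criterion above is the package's
  documented answer, not an inherited one.
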