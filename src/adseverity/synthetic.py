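"""Seeded synthetic inputs for every stage of the severity pipeline.

Three generators stand in for the restricted-access study data:

* :func:`make_phantom` — clean/noisy volume pairs on the 0-255 intensity
  scale (smooth ellipsoidal blobs plus additive noise), emulating the
  64 x 64 x 48 resting-state fMRI volumes the denoiser targets.
* :func:`make_multitask_problem` — multitask regression data with a
  planted row-sparse shared component P and column-sparse outlier
  component Q, the ground truth the robust multitask solver must recover.
* :func:`make_cohort` — a patients x features table with four
  class-conditional Gaussian feature distributions and per-patient
  integer MMSE scores drawn inside each generating class's band.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .denoise import Volume
from .mmse import CLASS_NAMES, SeverityClass, mmse_band
from .rmtfl import TaskDataset

__all__ = [
    "Phantom",
    "MultitaskTruth",
    "PatientCohort",
    "make_phantom",
    "make_multitask_problem",
    "make_cohort",
    "cohort_to_csv",
    "cohort_from_csv",
]


@dataclass(frozen=True)
class Phantom:
    """A clean volume, its noisy observation, and the generating noise level."""

    clean: Volume
    noisy: Volume
    noise_sigma: float
    seed: int


@dataclass(frozen=True)
class MultitaskTruth:
    """Planted ground truth behind a multitask regression problem."""

    P_true: np.ndarray  # features x tasks, row-sparse
    Q_true: np.ndarray  # features x tasks, column-sparse
    shared_support: frozenset[int]
    outlier_tasks: frozenset[int]
    noise_sd: float


@dataclass(frozen=True)
class PatientCohort:
    """Synthetic feature table with per-patient MMSE and generating class."""

    features: np.ndarray        # patients x n_features
    mmse: np.ndarray            # integer scores in [0, 30]
    classes: np.ndarray         # generating SeverityClass codes per patient
    class_means: np.ndarray     # 4 x n_features
    effect_size: float
    seed: int

    @property
    def n_patients(self) -> int:
        return self.features.shape[0]


def make_phantom(shape=(64, 64, 48), n_blobs: int = 5, noise_sigma: float = 15.0,
                 seed: int = 0, noise_model: str = "gaussian") -> Phantom:
    """Smooth ellipsoidal blobs on a uniform background, plus seeded noise.

    Intensities live on the 0-255 scale.  The background sits at 60 and
    blob amplitudes in [60, 160] keep typical noisy voxels away from the
    clip bounds, so the empirical noise SD matches ``noise_sigma``.
    ``noise_model`` is ``"gaussian"`` (additive, default) or ``"rician"``.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise ValueError(f"shape must have 3 positive dimensions, got {shape}")
    if n_blobs < 1:
        raise ValueError("n_blobs must be >= 1")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    clean = np.full(shape, 60.0)
    for _ in range(n_blobs):
        center = [rng.uniform(0.2 * s, 0.8 * s) for s in shape]
        axes = [rng.uniform(0.10 * s, 0.25 * s) for s in shape]
        amp = rng.uniform(60.0, 160.0)
        rho2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
        clean += amp * np.exp(-rho2)
    clean = np.clip(clean, 0.0, 255.0)
    if noise_sigma == 0:
        noisy = clean.copy()
    elif noise_model == "gaussian":
        noisy = clean + rng.normal(0.0, noise_sigma, shape)
    elif noise_model == "rician":
        n1 = rng.normal(0.0, noise_sigma, shape)
        n2 = rng.normal(0.0, noise_sigma, shape)
        noisy = np.sqrt((clean + n1) ** 2 + n2 ** 2)
    else:
        raise ValueError(f"unknown noise_model {noise_model!r}")
    noisy = np.clip(noisy, 0.0, 255.0)
    return Phantom(Volume(clean), Volume(noisy), float(noise_sigma), int(seed))


def make_multitask_problem(d: int = 50, m: int = 5, n_per_task: int = 100,
                           s_shared: int = 5, k_outlier: int = 1,
                           signal_scale: float = 1.0, noise_sd: float = 0.1,
                           seed: int = 0) -> tuple[TaskDataset, MultitaskTruth]:
    """Multitask regression with planted W = P + Q structure.

    Designs X_i (d x n) have i.i.d. standard-normal entries.  P has
    nonzero rows only on a random ``s_shared``-subset of features; Q has
    nonzero columns only on a random ``k_outlier``-subset of tasks;
    nonzero entries are random signs times ``signal_scale``.  Responses
    are y_i = X_i^T (p_i + q_i) + N(0, noise_sd^2).
    """
    if not 0 < s_shared <= d:
        raise ValueError(f"need 0 < s_shared <= d, got s_shared={s_shared}, d={d}")
    if not 0 <= k_outlier < m:
        raise ValueError(f"need 0 <= k_outlier < m, got k_outlier={k_outlier}, m={m}")
    if n_per_task < 1:
        raise ValueError("n_per_task must be >= 1")
    rng = np.random.default_rng(seed)
    support = rng.choice(d, size=s_shared, replace=False)
    outliers = rng.choice(m, size=k_outlier, replace=False) if k_outlier else np.array([], int)
    P = np.zeros((d, m))
    P[support, :] = signal_scale * rng.choice([-1.0, 1.0], size=(s_shared, m))
    Q = np.zeros((d, m))
    if k_outlier:
        Q[:, outliers] = signal_scale * rng.choice([-1.0, 1.0], size=(d, k_outlier))
    tasks = []
    for i in range(m):
        X = rng.standard_normal((d, n_per_task))
        y = X.T @ (P[:, i] + Q[:, i])
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, n_per_task)
        tasks.append((X, y))
    truth = MultitaskTruth(P, Q, frozenset(int(j) for j in support),
                           frozenset(int(i) for i in outliers), float(noise_sd))
    return TaskDataset(tasks), truth


#: study composition: low-dominant cohort with a small severe class
DEFAULT_PROPORTIONS = (0.69, 0.21, 0.092, 0.008)


def make_cohort(n_patients: int = 1000, n_features: int = 285,
                class_proportions=DEFAULT_PROPORTIONS, effect_size: float = 3.0,
                seed: int = 0, boundary: str = "less_severe") -> PatientCohort:
    """Class-conditional Gaussian feature table with matching MMSE scores.

    Each patient is assigned a severity class by ``class_proportions``;
    features are N(class mean, 1) with class means drawn i.i.d.
    N(0, effect_size^2) per feature (so ``effect_size`` is the
    per-feature dispersion of class means in within-class SD units, and
    ``effect_size=0`` collapses all class means to equality).  MMSE
    scores are integers drawn uniformly from the generating class's band
    under the chosen boundary convention.
    """
    props = np.asarray(class_proportions, dtype=float)
    if props.shape != (4,) or np.any(props < 0):
        raise ValueError("class_proportions must be 4 nonnegative entries")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"class_proportions must sum to 1, got {props.sum()!r}")
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    rng = np.random.default_rng(seed)
    class_means = effect_size * rng.standard_normal((4, n_features))
    classes = rng.choice(4, size=n_patients, p=props)
    features = class_means[classes] + rng.standard_normal((n_patients, n_features))
    mmse = np.empty(n_patients, dtype=int)
    for cls in SeverityClass:
        lo, hi = mmse_band(cls, boundary)
        mask = classes == int(cls)
        mmse[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
    return PatientCohort(features, mmse, classes.astype(int), class_means,
                         float(effect_size), int(seed))


def cohort_to_csv(cohort: PatientCohort, path) -> None:
    """Write patient_id, f1..fD, mmse, severity columns."""
    d = cohort.features.shape[1]
    df = pd.DataFrame(cohort.features, columns=[f"f{j + 1}" for j in range(d)])
    df.insert(0, "patient_id", np.arange(1, cohort.n_patients + 1))
    df["mmse"] = cohort.mmse
    df["severity"] = [CLASS_NAMES[c] for c in cohort.classes]
    df.to_csv(path, index=False)


def cohort_from_csv(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read back (features, mmse, severity codes) from :func:`cohort_to_csv`."""
    df = pd.read_csv(path)
    feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    features = df[feat_cols].to_numpy(dtype=float)
    mmse = df["mmse"].to_numpy(dtype=int)
    codes = np.array([CLASS_NAMES.index(s) for s in df["severity"]], dtype=int)
    return features, mmse, codes
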