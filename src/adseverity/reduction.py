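"""PCA feature reduction with a cumulative-explained-variance stopping rule.

Components of the mean-centered covariance eigendecomposition are kept
in descending eigenvalue order; the normalized cumulative sum of
eigenvalues

    NCSE(i) = sum_{n<=i} eigenvalue(n) / sum_{n<=N_f} eigenvalue(n)

selects the smallest i whose NCSE reaches the variance threshold
(default 98%).  On the study's 285-feature tables this rule keeps 167
components, a 41.4% reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EigenSpectrum",
    "ReductionResult",
    "pca_fit",
    "transform",
    "ncse",
    "select_components",
    "reduction_percent",
]

_EIG_CLIP = 1e-10  # eigenvalues below this are numerical zero


@dataclass(frozen=True)
class EigenSpectrum:
    """Descending eigenvalues, matching orthonormal components, and the removed mean."""

    eigenvalues: np.ndarray    # length N_f, descending, >= 0
    components: np.ndarray     # N_f x N_f, columns are eigenvectors
    mean_vector: np.ndarray

    @property
    def n_features(self) -> int:
        return self.eigenvalues.size


@dataclass(frozen=True)
class ReductionResult:
    n_selected: int
    ncse_at_selection: float
    reduced_table: np.ndarray  # patients x n_selected


def pca_fit(features: np.ndarray) -> EigenSpectrum:
    """Eigendecomposition of the sample covariance of mean-centered data.

    Eigenvalues use the unbiased (n-1) normalization; values below the
    numerical-zero clip are set to exactly 0.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("pca_fit needs a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD of the centered data is numerically safer than forming the covariance
    _, s, Vt = np.linalg.svd(Xc, full_matrices=True)
    eig = np.zeros(X.shape[1])
    eig[: s.size] = s ** 2 / (X.shape[0] - 1)
    eig[eig < _EIG_CLIP] = 0.0
    return EigenSpectrum(eig, Vt.T, mean)


def transform(spectrum: EigenSpectrum, features: np.ndarray, n_components: int) -> np.ndarray:
    """Project (possibly new) data onto the leading components."""
    X = np.asarray(features, dtype=float)
    return (X - spectrum.mean_vector) @ spectrum.components[:, :n_components]


def ncse(spectrum: EigenSpectrum, i: int) -> float:
    """Fraction of total variance captured by the first i components."""
    if not 1 <= i <= spectrum.n_features:
        raise ValueError(f"i must lie in [1, {spectrum.n_features}], got {i}")
    total = spectrum.eigenvalues.sum()
    if total <= 0:
        raise ValueError("total variance is zero; NCSE undefined")
    return float(spectrum.eigenvalues[:i].sum() / total)


def select_components(spectrum: EigenSpectrum, features: np.ndarray,
                      variance_threshold: float = 0.98) -> ReductionResult:
    """Smallest component count whose NCSE meets the threshold, plus the projection."""
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must lie in (0, 1]")
    total = spectrum.eigenvalues.sum()
    if total <= 0:
        raise ValueError("total variance is zero; nothing to select")
    cum = np.cumsum(spectrum.eigenvalues) / total
    # float cumsum can undershoot 1.0 by an ulp; the last entry is 1 by definition
    cum[-1] = 1.0
    n_selected = int(np.argmax(cum >= variance_threshold)) + 1
    return ReductionResult(n_selected, float(cum[n_selected - 1]),
                           transform(spectrum, features, n_selected))


def reduction_percent(total: int, retained: int) -> float:
    """Percent of features removed, to one decimal: 100*(total-retained)/total."""
    if not 1 <= retained <= total:
        raise ValueError(f"need 1 <= retained <= total, got retained={retained}, total={total}")
    return round(100.0 * (total - retained) / total, 1)
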