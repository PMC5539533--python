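"""PCA of pretreated fingerprint-region spectra.

Pretreatment follows the chemometric recipe: normalized 1800–600 cm^-1
spectra -> Savitzky–Golay first derivative (window 13, order 2) ->
column mean centering.  The decomposition itself is SVD-based (via
scikit-learn); explained-variance fractions are sigma_k^2 / sum(sigma_i^2)
of the centered matrix.

Component signs are arbitrary in any PCA; here each component is oriented so
its score has non-negative rank correlation with DPA (fibers mature with
time, so PC1 conventionally increases with DPA), falling back to making the
largest-magnitude loading positive when DPA is not supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.decomposition import PCA as _SKPCA

from .preprocess import PreprocessConfig, preprocess_sample, savgol_first_derivative
from .io import SpectralDataset

__all__ = [
    "PCAModel",
    "pca_pretreat",
    "fit_pca",
    "loo_cross_validation",
    "scores_vs_dpa",
]


@dataclass(frozen=True)
class PCAModel:
    """Fitted PCA: orthonormal loadings (components x variables), scores
    (samples x components), explained-variance fractions, and a pretreatment
    descriptor."""

    loadings: np.ndarray
    scores: np.ndarray
    explained_variance_fraction: np.ndarray
    n_components: int
    pretreatment: str = "savgol-deriv1(13,2) + mean-centering"

    @property
    def explained_variance_pct(self) -> np.ndarray:
        return 100.0 * self.explained_variance_fraction


def pca_pretreat(
    dataset: SpectralDataset, config: PreprocessConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Build the samples-by-variables matrix PCA is fit on.

    Returns ``(matrix, region_wavenumbers)``: first-derivative spectra of the
    normalized fingerprint region, column-mean-centered.
    """
    config = config or PreprocessConfig()
    if len(dataset) < 2:
        raise ValueError("PCA pretreatment needs >=2 samples")
    normalized = [preprocess_sample(s, config)[1] for s in dataset]
    wn = normalized[0].wavenumbers
    matrix = np.vstack([n.absorbance for n in normalized])
    deriv = savgol_first_derivative(
        matrix, wn, window=config.deriv_window, polyorder=config.deriv_polyorder
    )
    centered = deriv - deriv.mean(axis=0, keepdims=True)
    return centered, wn


def _orient(loadings, scores, dpa=None):
    """Fix the arbitrary per-component sign (see module docstring)."""
    for k in range(loadings.shape[0]):
        if dpa is not None:
            rho = spearmanr(scores[:, k], dpa).statistic
            flip = np.nan_to_num(rho) < 0
        else:
            flip = loadings[k, np.argmax(np.abs(loadings[k]))] < 0
        if flip:
            loadings[k] *= -1
            scores[:, k] *= -1
    return loadings, scores


def fit_pca(
    matrix: np.ndarray, n_components: int, dpa: np.ndarray | None = None
) -> PCAModel:
    """SVD-based PCA of a (pre-centered or raw) samples-by-variables matrix.

    ``explained_variance_fraction[k]`` is sigma_k^2 over the total variance of
    the centered matrix.
    """
    matrix = np.asarray(matrix, dtype=float)
    n, p = matrix.shape
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples-1, variables)="
            f"{min(n - 1, p)}"
        )
    centered = matrix - matrix.mean(axis=0, keepdims=True)
    if not np.any(centered):
        raise ValueError("matrix has zero variance; PCA is degenerate")
    sk = _SKPCA(n_components=n_components, svd_solver="full")
    scores = sk.fit_transform(matrix)
    loadings, scores = _orient(sk.components_.copy(), scores.copy(), dpa)
    return PCAModel(
        loadings=loadings,
        scores=scores,
        explained_variance_fraction=sk.explained_variance_ratio_.copy(),
        n_components=n_components,
    )


def loo_cross_validation(matrix: np.ndarray, max_components: int) -> np.ndarray:
    """Leave-one-out PRESS for k = 1..max_components.

    Each sample is held out in turn; PCA is fit on the rest, the held-out
    sample is projected onto the first k loadings and reconstructed, and its
    squared reconstruction error accumulated.  The naive project-then-
    reconstruct scheme is used (optimistically biased relative to row-wise
    cross-validation schemes, but the conventional quick diagnostic).
    """
    matrix = np.asarray(matrix, dtype=float)
    n, p = matrix.shape
    if n < 3:
        raise ValueError("leave-one-out cross-validation needs >=3 samples")
    if max_components > min(n - 2, p):
        raise ValueError(
            f"max_components={max_components} exceeds min(samples-2, variables)="
            f"{min(n - 2, p)}"
        )
    press = np.zeros(max_components)
    for i in range(n):
        train = np.delete(matrix, i, axis=0)
        mean = train.mean(axis=0)
        _, _, vt = np.linalg.svd(train - mean, full_matrices=False)
        resid = matrix[i] - mean
        coords = vt @ resid
        for k in range(1, max_components + 1):
            recon = coords[:k] @ vt[:k]
            press[k - 1] += float(np.sum((resid - recon) ** 2))
    return press


def scores_vs_dpa(model: PCAModel, dataset: SpectralDataset) -> pd.DataFrame:
    """Join PC scores with sample metadata, ordered by genotype then DPA."""
    if model.scores.shape[0] != len(dataset):
        raise ValueError(
            f"model fitted on {model.scores.shape[0]} samples but dataset has "
            f"{len(dataset)}"
        )
    df = dataset.metadata_frame()
    for k in range(min(model.n_components, 2)):
        df[f"pc{k + 1}_score"] = model.scores[:, k]
    return df.sort_values(["genotype", "dpa", "replicate"], kind="stable").reset_index(
        drop=True
    )
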