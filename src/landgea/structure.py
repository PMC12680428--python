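"""Genotype PCA and the SNP-subset structure-correlation permutation test."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PcaResult:
    scores: np.ndarray  # individuals x axes (U * S)
    eigenvalues: np.ndarray  # descending, = singular_values^2 / (n - 1)
    explained_ratio: np.ndarray
    scaling: str


def _scale_matrix(X: np.ndarray, scaling: str) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    if scaling == "center":
        return Xc
    if scaling == "center_unit":
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0  # constant columns carry no signal; leave centered
        return Xc / sd
    raise ValueError("scaling must be 'center' or 'center_unit'")


def pca_genotypes(dosages: np.ndarray, scaling: str = "center_unit") -> PcaResult:
    """SVD principal components of an imputed dosage matrix.

    Scores are left singular vectors scaled by singular values, so their
    column variances equal the eigenvalues.
    """
    X = np.asarray(dosages, float)
    if np.isnan(X).any():
        raise ValueError("dosage matrix has missing cells; impute first")
    Xs = _scale_matrix(X, scaling)
    if not Xs.any():
        raise ValueError("constant matrix has no principal components")
    U, S, _ = np.linalg.svd(Xs, full_matrices=False)
    eig = S**2 / (X.shape[0] - 1)
    return PcaResult(
        scores=U * S,
        eigenvalues=eig,
        explained_ratio=eig / eig.sum(),
        scaling=scaling,
    )


def _pc1(dosages: np.ndarray, scaling: str) -> np.ndarray:
    return pca_genotypes(dosages, scaling=scaling).scores[:, 0]


def pc_subset_correlation_test(
    dosages: np.ndarray,
    subset_loci: np.ndarray,
    n_perm: int = 10_000,
    scaling: str = "center_unit",
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Does a locus subset recover the structure of the full panel?

    Compares PC1 of the full-panel PCA with PC1 of a subset-only PCA
    (after sign alignment; SVD signs are arbitrary) via squared Pearson
    correlation, and locates the observed R^2 in a null distribution from
    ``n_perm`` random same-size subsets.

    Returns ``(R^2, p)`` with the add-one permutation convention.
    """
    subset_loci = np.asarray(subset_loci)
    if subset_loci.size < 2:
        raise ValueError("subset must contain >= 2 loci")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X = np.asarray(dosages, float)
    full = _pc1(X, scaling)

    def r2_for(cols: np.ndarray) -> float:
        sub = _pc1(X[:, cols], scaling)
        return float(np.corrcoef(full, sub)[0, 1] ** 2)

    r2_obs = r2_for(subset_loci)
    m = X.shape[1]
    k = subset_loci.size
    count = 0
    for _ in range(n_perm):
        if r2_for(rng.choice(m, size=k, replace=False)) >= r2_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return r2_obs, p


def procrustes_similarity(scores_a: np.ndarray, scores_b: np.ndarray, n_axes: int = 2) -> float:
    """Multi-axis similarity between two score matrices (1 - Procrustes m^2)."""
    from scipy.spatial import procrustes

    _, _, disparity = procrustes(scores_a[:, :n_axes], scores_b[:, :n_axes])
    return 1.0 - float(disparity)
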