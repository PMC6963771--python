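"""Two-track dimensionality reduction for degenerate ensembles (N ≪ D).

Track one is standard normalized PCA computed with a truncated SVD; track two
projects the same standardized data onto leading eigenvectors of a symmetric
Gaussian random matrix of the same dimension as the correlation matrix.  All
ensemble statistics use divisor-N (population) conventions so that the
covariance of standardized data is exactly the correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .structures import CoordinateMatrix

__all__ = [
    "StandardizedMatrix",
    "EigenDecomposition",
    "ProjectionResult",
    "RandomMatrixSpec",
    "standardize",
    "covariance_matrix",
    "correlation_matrix",
    "eigendecompose",
    "pca_project",
    "random_symmetric_matrix",
    "random_project",
]


@dataclass
class StandardizedMatrix:
    """Column-standardized data: each column has mean 0 and (divisor-N) std 1."""

    values: np.ndarray
    column_means: np.ndarray
    column_stds: np.ndarray
    row_labels: list | None = None


@dataclass
class EigenDecomposition:
    """Eigenvalues (descending) and matching orthonormal eigenvector columns."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray


@dataclass
class ProjectionResult:
    """k-dimensional scores per structure plus the basis that produced them."""

    scores: np.ndarray
    basis: np.ndarray
    spectrum: np.ndarray
    method: str
    k: int
    seed: int | None = None
    row_labels: list | None = None


@dataclass(frozen=True)
class RandomMatrixSpec:
    """Reproducible recipe for a symmetric Gaussian random matrix."""

    dimension: int
    seed: int
    ensemble: str = "gaussian_symmetric"


def _as_values(matrix) -> tuple:
    if isinstance(matrix, CoordinateMatrix):
        return matrix.values, matrix.row_labels, matrix.atom_keys
    if isinstance(matrix, StandardizedMatrix):
        return matrix.values, matrix.row_labels, None
    return np.asarray(matrix, dtype=float), None, None


def standardize(matrix) -> StandardizedMatrix:
    """Center and scale each column to zero mean and unit divisor-N std.

    Raises on (near-)zero-variance columns; when the input is a
    CoordinateMatrix the offending atom keys are listed.
    """
    values, labels, atom_keys = _as_values(matrix)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need an N x D matrix with N >= 2")
    mu = values.mean(axis=0)
    sigma = values.std(axis=0)  # divisor N
    bad = np.flatnonzero(sigma <= 1e-12)
    if bad.size:
        if atom_keys is not None:
            names = sorted({str(atom_keys[i // 3]) for i in bad})
            raise ValueError(f"zero-variance columns for atoms: {', '.join(names)}")
        raise ValueError(f"zero-variance columns at indices {bad.tolist()}")
    return StandardizedMatrix((values - mu) / sigma, mu, sigma, labels)


def covariance_matrix(matrix) -> np.ndarray:
    """Population (divisor-N) covariance of the columns of an N×D matrix."""
    values, _, _ = _as_values(matrix)
    if values.shape[0] < 2:
        raise ValueError("need N >= 2 rows")
    centered = values - values.mean(axis=0)
    cov = centered.T @ centered / values.shape[0]
    return (cov + cov.T) / 2.0


def correlation_matrix(cov: np.ndarray) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    diag = np.diag(cov)
    if np.any(diag <= 0):
        raise ValueError("covariance has zero (or negative) diagonal entries")
    scale = np.sqrt(diag)
    corr = cov / np.outer(scale, scale)
    np.fill_diagonal(corr, 1.0)
    return np.clip((corr + corr.T) / 2.0, -1.0, 1.0)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip columns so each eigenvector's largest-magnitude component is positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def eigendecompose(matrix: np.ndarray, atol: float = 1e-8) -> EigenDecomposition:
    """Full symmetric eigendecomposition, eigenvalues sorted descending.

    The input is symmetrized by (A + Aᵀ)/2; asymmetry beyond ``atol`` raises.
    """
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrix must be square")
    if np.abs(a - a.T).max() > atol:
        raise ValueError("matrix is not symmetric within tolerance")
    sym = (a + a.T) / 2.0
    w, v = np.linalg.eigh(sym)
    order = np.argsort(w, kind="stable")[::-1]
    return EigenDecomposition(w[order], _fix_signs(v[:, order]))


def pca_project(std: StandardizedMatrix, k: int = 2) -> ProjectionResult:
    """Principal-component scores via truncated SVD of the standardized data.

    Equivalent to projecting onto the top-k eigenvectors of the correlation
    matrix, but never forms the D×D matrix (N ≪ D safe). The spectrum holds
    the top-k correlation-matrix eigenvalues (squared singular values / N).
    """
    x = std.values
    n, d = x.shape
    if not 1 <= k <= min(n - 1, d):
        raise ValueError(f"k={k} out of range [1, {min(n - 1, d)}]")
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    basis = _fix_signs(vt[:k].T)
    return ProjectionResult(
        scores=x @ basis,
        basis=basis,
        spectrum=s[:k] ** 2 / n,
        method="pca_tsvd",
        k=k,
        row_labels=std.row_labels,
    )


def random_symmetric_matrix(spec: RandomMatrixSpec) -> np.ndarray:
    """Symmetric matrix with i.i.d. standard Gaussian entries on and above the
    diagonal (GOE up to scaling); identical for identical specs."""
    if spec.ensemble != "gaussian_symmetric":
        raise ValueError(f"unknown ensemble {spec.ensemble!r}")
    if spec.dimension < 2:
        raise ValueError("dimension must be >= 2")
    rng = np.random.default_rng(spec.seed)
    g = rng.standard_normal((spec.dimension, spec.dimension))
    upper = np.triu(g)
    return upper + upper.T - np.diag(np.diag(g))


def random_project(std: StandardizedMatrix, seed: int, k: int = 2) -> ProjectionResult:
    """Project standardized data onto the top-k eigenvectors of a seeded
    symmetric Gaussian random matrix of dimension D.

    Under the rotation-invariant Gaussian ensemble this basis is a uniformly
    random orthonormal k-frame, so the projection is a random low-dimensional
    shadow of the full-dimensional cloud.
    """
    x = std.values
    d = x.shape[1]
    if not 1 <= k <= d:
        raise ValueError(f"k={k} out of range [1, {d}]")
    m = random_symmetric_matrix(RandomMatrixSpec(dimension=d, seed=seed))
    # only the k largest eigenpairs are needed; syevr subset keeps D~2000 fast
    w, v = scipy.linalg.eigh(m, subset_by_index=[d - k, d - 1])
    order = np.argsort(w, kind="stable")[::-1]
    basis = _fix_signs(v[:, order])
    return ProjectionResult(
        scores=x @ basis,
        basis=basis,
        spectrum=w[order],
        method="random_projection",
        k=k,
        seed=seed,
        row_labels=std.row_labels,
    )
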