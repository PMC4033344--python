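"""Feature extraction from gait templates.

The workhorse is two-dimensional PCA (2DPCA), which operates on the
template images directly instead of flattening them.  For training
templates ``G_1 .. G_M`` (each ``m x n``) with element-wise mean ``Gbar``,
the image covariance matrix is the ``n x n`` sum

    C_t = sum_i (G_i - Gbar)^T (G_i - Gbar)

(the printed, unnormalized form; dividing by M rescales the eigenvalues but
leaves eigenvectors, projections and distances unchanged).  The projection
axes ``W_1 .. W_d`` are the unit eigenvectors of ``C_t`` with the largest
eigenvalues, each axis maximizing the trace of the projected scatter
``W^T C_t W``.  A template projects to the ``m x d`` feature matrix with
columns ``Y_k = G W_k``, and the distance between two feature matrices is
the sum over k of the Euclidean norms of the column differences.

``VectorizedPCA`` is the classical baseline: flatten each template to an
``mn``-vector, eigendecompose the ``mn x mn`` covariance of the centered
vectors, project onto the top-d axes.  It exists for accuracy/cost
comparisons against 2DPCA; its covariance is quadratically larger.

Both extractors follow the scikit-learn estimator protocol (``fit`` /
``transform`` / ``inverse_transform``) over stacks of template images
shaped ``(M, m, n)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .templates import GaitTemplate

__all__ = [
    "ProjectionBasis",
    "TwoDPCA",
    "VectorizedPCA",
    "fit_basis",
    "scatter_trace",
    "project",
    "feature_distance",
    "reconstruct",
    "fit_pca_baseline",
]

_UNIT_TOL = 1e-6


def _as_image_stack(templates) -> np.ndarray:
    """Coerce a list of GaitTemplate / 2-D arrays or a 3-D array to (M, m, n)."""
    if isinstance(templates, np.ndarray) and templates.ndim == 3:
        return templates.astype(float)
    arrays = []
    for t in templates:
        a = t.values if isinstance(t, GaitTemplate) else np.asarray(t, float)
        if a.ndim != 2:
            raise ValueError("each template must be a 2-D image")
        arrays.append(a)
    if not arrays:
        raise ValueError("empty template list")
    shape = arrays[0].shape
    for i, a in enumerate(arrays):
        if a.shape != shape:
            raise ValueError(f"template {i} has shape {a.shape}, expected {shape}")
    return np.stack(arrays)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude component positive (deterministic
    serialization; distances and reconstructions are sign-invariant)."""
    idx = np.abs(vectors).argmax(axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


@dataclass(frozen=True)
class ProjectionBasis:
    """Fitted 2DPCA basis: mean template, image covariance and top-d axes.

    ``components`` holds the unit eigenvectors as columns (n x d), ordered
    by descending eigenvalue; ``eigenvalues`` holds all n eigenvalues of
    the (unnormalized) image covariance.
    """

    mean_template: np.ndarray
    covariance: np.ndarray
    eigenvalues: np.ndarray
    components: np.ndarray
    n_components: int

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.mean_template.shape


class TwoDPCA(TransformerMixin, BaseEstimator):
    """2DPCA feature extractor over template images.

    Parameters
    ----------
    n_components : int, default 20
        Number of projection axes d (1 <= d <= n, the image width).

    Attributes
    ----------
    mean_ : ndarray (m, n)
        Element-wise mean training template.
    covariance_ : ndarray (n, n)
        Image covariance C_t (unnormalized sum over training templates).
    eigenvalues_ : ndarray (n,)
        All eigenvalues of C_t, descending.
    components_ : ndarray (n, d)
        Unit eigenvectors as columns, eigenvalue order, sign-fixed.
    basis_ : ProjectionBasis
        The fitted basis as a serializable value object.
    """

    def __init__(self, n_components: int = 20):
        self.n_components = n_components

    def fit(self, X, y=None) -> "TwoDPCA":
        stack = _as_image_stack(X)
        M, m, n = stack.shape
        if M < 2:
            raise ValueError("need at least 2 templates to fit a 2DPCA basis")
        d = self.n_components
        if not 1 <= d <= n:
            raise ValueError(f"n_components must be in [1, {n}], got {d}")
        mean = stack.mean(axis=0)
        centered = stack - mean
        # C_t = sum_i (G_i - mean)^T (G_i - mean), an n x n PSD matrix
        cov = np.einsum("imn,imk->nk", centered, centered, optimize=True)
        cov = (cov + cov.T) / 2.0
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = evals[order]
        evecs = _fix_signs(evecs[:, order])
        self.mean_ = mean
        self.covariance_ = cov
        self.eigenvalues_ = evals
        self.components_ = evecs[:, :d]
        self.basis_ = ProjectionBasis(
            mean_template=mean,
            covariance=cov,
            eigenvalues=evals,
            components=self.components_,
            n_components=d,
        )
        return self

    def transform(self, X) -> np.ndarray:
        """Project templates onto the basis: (M, m, n) -> (M, m, d)."""
        check_is_fitted(self, "components_")
        stack = _as_image_stack(X)
        if stack.shape[1:] != self.mean_.shape:
            raise ValueError(
                f"template shape {stack.shape[1:]} does not match basis {self.mean_.shape}"
            )
        return stack @ self.components_

    def inverse_transform(self, Y) -> np.ndarray:
        """Rank-d reconstruction: (M, m, d) -> (M, m, n)."""
        check_is_fitted(self, "components_")
        Y = np.asarray(Y, float)
        if Y.shape[-1] != self.components_.shape[1]:
            raise ValueError("feature column count does not match basis d")
        return Y @ self.components_.T

    def scatter_trace(self, w: np.ndarray) -> float:
        """Projected-scatter trace w^T C_t w for a unit candidate axis."""
        check_is_fitted(self, "covariance_")
        w = np.asarray(w, float).ravel()
        if abs(np.linalg.norm(w) - 1.0) > _UNIT_TOL:
            raise ValueError("candidate axis must be a unit vector")
        return float(w @ self.covariance_ @ w)


class VectorizedPCA(TransformerMixin, BaseEstimator):
    """Classical PCA over flattened templates (the 1-D baseline).

    Eigendecomposes the full ``mn x mn`` covariance of the centered,
    flattened training templates; features are d-vectors compared with the
    plain Euclidean distance.
    """

    def __init__(self, n_components: int = 20):
        self.n_components = n_components

    def fit(self, X, y=None) -> "VectorizedPCA":
        stack = _as_image_stack(X)
        M, m, n = stack.shape
        if M < 2:
            raise ValueError("need at least 2 templates to fit PCA")
        flat = stack.reshape(M, m * n)
        self.mean_ = flat.mean(axis=0)
        centered = flat - self.mean_
        cov = centered.T @ centered
        cov = (cov + cov.T) / 2.0
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = evals[order]
        evecs = _fix_signs(evecs[:, order])
        d = self.n_components
        rank = int(np.sum(evals > max(evals[0], 0) * 1e-10)) if evals.size else 0
        if d > rank:
            raise ValueError(f"n_components {d} exceeds covariance rank {rank}")
        self.eigenvalues_ = evals
        self.components_ = evecs[:, :d]
        self.image_shape_ = (m, n)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "components_")
        stack = _as_image_stack(X)
        if stack.shape[1:] != self.image_shape_:
            raise ValueError("template shape does not match fitted basis")
        flat = stack.reshape(stack.shape[0], -1)
        return (flat - self.mean_) @ self.components_

    def inverse_transform(self, Y) -> np.ndarray:
        check_is_fitted(self, "components_")
        Y = np.asarray(Y, float)
        flat = Y @ self.components_.T + self.mean_
        return flat.reshape(Y.shape[0], *self.image_shape_)


# ---------------------------------------------------------------------------
# function-style wrappers over the estimators


def fit_basis(templates, d: int = 20) -> ProjectionBasis:
    """Fit a 2DPCA projection basis on training templates."""
    return TwoDPCA(n_components=d).fit(templates).basis_


def _estimator_from_basis(basis: ProjectionBasis) -> TwoDPCA:
    est = TwoDPCA(n_components=basis.n_components)
    est.mean_ = basis.mean_template
    est.covariance_ = basis.covariance
    est.eigenvalues_ = basis.eigenvalues
    est.components_ = basis.components
    est.basis_ = basis
    return est


def scatter_trace(basis: ProjectionBasis, w: np.ndarray) -> float:
    """Trace of the projected scatter for a candidate unit axis."""
    return _estimator_from_basis(basis).scatter_trace(w)


def project(template, basis: ProjectionBasis) -> np.ndarray:
    """Feature matrix Y (m x d) of one template: Y_k = G W_k."""
    G = template.values if isinstance(template, GaitTemplate) else np.asarray(template, float)
    return _estimator_from_basis(basis).transform(G[None])[0]


def feature_distance(Ya: np.ndarray, Yb: np.ndarray) -> float:
    """Distance between feature matrices: sum over columns of Euclidean norms."""
    Ya = np.asarray(Ya, float)
    Yb = np.asarray(Yb, float)
    if Ya.shape != Yb.shape:
        raise ValueError(f"feature shape mismatch: {Ya.shape} vs {Yb.shape}")
    if Ya.ndim == 1:  # vectorized-PCA features are plain d-vectors
        return float(np.linalg.norm(Ya - Yb))
    return float(np.linalg.norm(Ya - Yb, axis=0).sum())


def reconstruct(Y: np.ndarray, basis: ProjectionBasis, *, terms: bool = False):
    """Rank-d reconstruction ``sum_k Y_k W_k^T`` of a feature matrix.

    With ``terms=True`` the d rank-one sub-images ``Y_k W_k^T`` are returned
    as a (d, m, n) stack instead of their sum.
    """
    Y = np.asarray(Y, float)
    if Y.ndim != 2 or Y.shape[1] > basis.components.shape[1]:
        raise ValueError("feature matrix does not match basis")
    W = basis.components[:, : Y.shape[1]]
    if terms:
        return np.einsum("mk,nk->kmn", Y, W)
    return Y @ W.T


def fit_pca_baseline(templates, d: int = 20) -> VectorizedPCA:
    """Fit the flattened-image PCA baseline; returns the fitted estimator."""
    return VectorizedPCA(n_components=d).fit(templates)
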