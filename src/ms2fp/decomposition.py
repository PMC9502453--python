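"""Sparse principal component analysis of binned spectral matrices.

The binned matrix is ~97–99% zeros; ordinary PCA loadings mix thousands of
m/z bins, whereas sparse PCA constrains each component to a few bins,
keeping the low-dimensional scores interpretable while retaining most of
the variance.  Two sparsity parameterisations are exposed:

* ``penalty`` — an elastic-net style L1 weight (delegated to
  scikit-learn's ``SparsePCA``); ``penalty=0`` reduces to ordinary PCA and
  the scores then match an eigendecomposition oracle up to column sign.
* ``n_nonzero`` — a per-component cardinality bound, implemented by
  truncated power iteration with deflation.

Because sparse components are not orthogonal, explained variance is
computed as the QR-adjusted variance of the score matrix, which never
exceeds the total variance.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA, SparsePCA
from sklearn.utils.validation import check_is_fitted

from .io import SpectralMatrix


def _as_dense(X) -> np.ndarray:
    if isinstance(X, SpectralMatrix):
        X = X.X
    if sp.issparse(X):
        X = X.toarray()
    return np.asarray(X, dtype=float)


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|value| entry positive."""
    out = loadings.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        if col.any():
            i = int(np.argmax(np.abs(col)))
            if col[i] < 0:
                out[:, j] = -col
    return out


def _adjusted_variance(scores: np.ndarray) -> np.ndarray:
    """Per-component adjusted variance via QR of the score matrix.

    For non-orthogonal components the marginal variance of component k is
    the squared k-th diagonal of R in S = QR, divided by (n - 1); this
    removes variance already captured by earlier components.
    """
    n = scores.shape[0]
    if n < 2:
        return np.zeros(scores.shape[1])
    _, R = np.linalg.qr(scores)
    return np.diag(R) ** 2 / (n - 1)


def _truncated_power_spca(
    Xc: np.ndarray, k: int, n_nonzero: int, seed: Optional[int]
) -> np.ndarray:
    """Cardinality-constrained SPCA: power iteration with hard thresholding
    (keep the n_nonzero largest-|.| loading entries), deflating after each
    component."""
    rng = np.random.default_rng(seed)
    n, p = Xc.shape
    X = Xc.copy()
    loadings = np.zeros((p, k))
    for comp in range(k):
        v = rng.standard_normal(p)
        v /= np.linalg.norm(v)
        for _ in range(100):
            u = X @ v
            w = X.T @ u
            norm = np.linalg.norm(w)
            if norm < 1e-12:
                break
            w /= norm
            if n_nonzero < p:
                keep = np.argpartition(np.abs(w), p - n_nonzero)[p - n_nonzero:]
                mask = np.zeros(p, dtype=bool)
                mask[keep] = True
                w = np.where(mask, w, 0.0)
                nw = np.linalg.norm(w)
                if nw < 1e-12:
                    break
                w /= nw
            if np.linalg.norm(w - v) < 1e-10:
                v = w
                break
            v = w
        loadings[:, comp] = v
        s = X @ v
        X = X - np.outer(s, v)  # deflate
    return loadings


class SparseSpectralPCA(BaseEstimator, TransformerMixin):
    """Sparse PCA transformer for spectral matrices.

    Parameters
    ----------
    n_components : int
        Number of components k (must not exceed min(n_samples, n_features)).
    penalty : float, default 0.0
        L1 sparsity weight; 0 gives ordinary PCA.
    n_nonzero : int or None
        Per-component cardinality bound; overrides ``penalty`` when set.
    random_state : int or None
        Seed for the iterative solvers.

    Attributes
    ----------
    loadings_ : (n_features, k) ndarray
    scores_ : (n_samples, k) ndarray — training scores
    mean_ : (n_features,) ndarray — training column means
    explained_variance_ratio_ : (k,) ndarray
    cumulative_explained_variance_ : (k,) ndarray
    """

    def __init__(
        self,
        n_components: int = 2,
        penalty: float = 0.0,
        n_nonzero: Optional[int] = None,
        random_state: Optional[int] = 0,
    ):
        self.n_components = n_components
        self.penalty = penalty
        self.n_nonzero = n_nonzero
        self.random_state = random_state

    def fit(self, X, y=None) -> "SparseSpectralPCA":
        X = _as_dense(X)
        n, p = X.shape
        k = self.n_components
        if k > min(n, p):
            raise ValueError(
                f"n_components={k} exceeds min(n_samples, n_features)={min(n, p)}"
            )
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_

        if self.n_nonzero is not None:
            loadings = _truncated_power_spca(Xc, k, self.n_nonzero, self.random_state)
        elif self.penalty == 0.0:
            pca = PCA(n_components=k, svd_solver="full")
            pca.fit(X)
            loadings = pca.components_.T
        else:
            spca = SparsePCA(
                n_components=k,
                alpha=self.penalty,
                ridge_alpha=0.0,
                random_state=self.random_state,
                max_iter=500,
            )
            spca.fit(Xc)
            loadings = spca.components_.T
            norms = np.linalg.norm(loadings, axis=0)
            norms[norms == 0] = 1.0
            loadings = loadings / norms

        loadings = _fix_signs(loadings)
        scores = Xc @ loadings
        # order components by adjusted variance, descending (stable)
        adj = _adjusted_variance(scores)
        order = np.argsort(-adj, kind="stable")
        loadings, scores, adj = loadings[:, order], scores[:, order], adj[order]

        total_var = np.var(Xc, axis=0, ddof=1).sum() if n > 1 else 0.0
        if total_var > 0:
            evr = adj / total_var
        else:
            evr = np.zeros(k)
        self.loadings_ = loadings
        self.scores_ = scores
        self.explained_variance_ratio_ = evr
        self.cumulative_explained_variance_ = np.cumsum(evr)
        return self

    def transform(self, X) -> np.ndarray:
        """Project (held-out) spectra: (X - training mean) @ loadings."""
        check_is_fitted(self, "loadings_")
        X = _as_dense(X)
        if X.shape[1] != self.loadings_.shape[0]:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.loadings_.shape[0]}"
            )
        return (X - self.mean_) @ self.loadings_


def fit_spca(
    matrix,
    k: int,
    sparsity: float = 0.0,
    seed: Optional[int] = 0,
    n_nonzero: Optional[int] = None,
) -> SparseSpectralPCA:
    """Functional wrapper over :class:`SparseSpectralPCA`."""
    model = SparseSpectralPCA(
        n_components=k, penalty=sparsity, n_nonzero=n_nonzero, random_state=seed
    )
    return model.fit(matrix)


def select_k(cumulative_evr: np.ndarray, target: float) -> int:
    """Smallest k whose cumulative explained variance reaches ``target``.

    If the target is unreachable the maximum k is returned with a warning.
    """
    if not 0 < target <= 1:
        raise ValueError("target must be in (0, 1]")
    cum = np.asarray(cumulative_evr, dtype=float)
    idx = np.nonzero(cum >= target - 1e-12)[0]
    if idx.size == 0:
        warnings.warn(
            f"target {target} unreachable (max cumulative EVR {cum[-1]:.4f}); "
            "returning all components",
            stacklevel=2,
        )
        return len(cum)
    return int(idx[0]) + 1
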