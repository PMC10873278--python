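"""Scikit-learn style estimators for mortality-profile heterogeneity.

The cause-of-death inequality index of a share vector p over k mutually
exclusive causes is the quadratic form

    I = sum_i sum_j d_ij p_i p_j,

the average expected dissimilarity between the causes of two independently
drawn deaths, where d_ij in [0, 1] is a symmetric, zero-diagonal cause
dissimilarity (here typically the normalised classification-tree distance).
With all off-diagonal d_ij equal to 1 the index reduces to Simpson (Gini-
Simpson) diversity S = 1 - sum_c p_c^2, the probability that two random
deaths have different causes.  The index decomposes exactly by cause:

    I = sum_c p_c * I_c = sum_c C_c,      I_c = sum_i d_ci p_i,

so C_c = p_c I_c is the additive contribution of cause c (C_c = p_c (1 - p_c)
in the Simpson case).

Both estimators are stateless transformers over row-wise profiles: ``X`` is
an ``(n_profiles, k)`` array of death shares (rows renormalised to sum 1
within a tolerance), and ``transform`` maps it to an ``(n_profiles, 1)``
column of index values, so they compose with sklearn pipelines and unions.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .exceptions import AlignmentError, ProfileError

__all__ = ["CodInequality", "SimpsonDiversity"]

#: shares must sum to 1 within this before silent renormalisation
RENORM_TOL = 1e-6


def validate_shares(X, tol: float = RENORM_TOL) -> np.ndarray:
    """Validate and renormalise an (n, k) array of death shares.

    Rows must be non-negative and sum to 1 within ``tol``; rows inside the
    tolerance are renormalised exactly, rows outside it raise
    :class:`ProfileError`.
    """
    X = check_array(X, dtype=float, ensure_2d=True, ensure_min_features=1)
    if np.any(X < -1e-12):
        raise ProfileError("death shares must be non-negative")
    X = np.clip(X, 0.0, None)
    sums = X.sum(axis=1)
    bad = np.abs(sums - 1.0) > tol
    if np.any(bad):
        raise ProfileError(
            f"{int(bad.sum())} profile row(s) have shares summing to "
            f"{sums[bad][:5]} (must equal 1 within {tol}); normalise counts "
            "explicitly before constructing shares"
        )
    return X / sums[:, None]


class CodInequality(TransformerMixin, BaseEstimator):
    """Cause-of-death inequality index I = p' D p.

    Parameters
    ----------
    dissimilarity : array-like of shape (k, k), DissimilarityMatrix, or None
        Symmetric cause dissimilarity matrix with zero diagonal and entries
        in [0, 1], in the same cause order as the columns of ``X``.  ``None``
        uses the unit matrix (all off-diagonal 1), i.e. Simpson diversity.

    Attributes
    ----------
    dissimilarity_ : ndarray of shape (k, k)
        Validated dissimilarity matrix used by ``transform``.
    n_features_in_ : int
        Number of causes k.

    Examples
    --------
    >>> import numpy as np
    >>> D = np.full((3, 3), 2 / 3); np.fill_diagonal(D, 0.0)
    >>> est = CodInequality(dissimilarity=D).fit(np.full((1, 3), 1 / 3))
    >>> float(est.transform(np.full((1, 3), 1 / 3))[0, 0])  # doctest: +ELLIPSIS
    0.444...
    """

    def __init__(self, dissimilarity=None):
        self.dissimilarity = dissimilarity

    def _resolve_dissimilarity(self, k: int) -> np.ndarray:
        if self.dissimilarity is None:
            D = np.ones((k, k)) - np.eye(k)
            return D
        D = np.asarray(getattr(self.dissimilarity, "values", self.dissimilarity), dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise AlignmentError(f"dissimilarity must be square, got shape {D.shape}")
        if D.shape[0] != k:
            raise AlignmentError(
                f"dissimilarity is {D.shape[0]}x{D.shape[0]} but profiles have "
                f"{k} causes"
            )
        if not np.allclose(D, D.T, atol=1e-12):
            raise AlignmentError("dissimilarity matrix must be symmetric")
        if np.any(np.abs(np.diag(D)) > 1e-12):
            raise AlignmentError("dissimilarity matrix must have zero diagonal")
        if D.min() < -1e-12 or D.max() > 1 + 1e-12:
            raise AlignmentError("dissimilarities must lie in [0, 1]")
        return D

    def fit(self, X, y=None):
        X = validate_shares(X)
        self.n_features_in_ = X.shape[1]
        self.dissimilarity_ = self._resolve_dissimilarity(self.n_features_in_)
        return self

    def _check_X(self, X) -> np.ndarray:
        check_is_fitted(self, "dissimilarity_")
        X = validate_shares(X)
        if X.shape[1] != self.n_features_in_:
            raise AlignmentError(
                f"X has {X.shape[1]} causes, estimator was fitted with "
                f"{self.n_features_in_}"
            )
        return X

    def mean_distances(self, X) -> np.ndarray:
        """Per-cause share-weighted mean distances I_c = sum_i d_ci p_i,
        shape (n, k)."""
        X = self._check_X(X)
        return X @ self.dissimilarity_.T

    def contributions(self, X) -> np.ndarray:
        """Per-cause additive contributions C_c = p_c I_c, shape (n, k).
        Rows sum to the index value."""
        X = self._check_X(X)
        return X * (X @ self.dissimilarity_.T)

    def transform(self, X) -> np.ndarray:
        """Index values, shape (n, 1)."""
        return self.contributions(X).sum(axis=1, keepdims=True)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(["cod_inequality"], dtype=object)


class SimpsonDiversity(CodInequality):
    """Simpson (Gini-Simpson) diversity S = 1 - sum_c p_c^2.

    The special case of :class:`CodInequality` in which every pair of
    distinct causes is maximally dissimilar (d_ij = 1 for i != j); S is the
    probability that two independently drawn deaths have different causes.
    """

    def __init__(self):
        super().__init__(dissimilarity=None)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(["simpson_diversity"], dtype=object)
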