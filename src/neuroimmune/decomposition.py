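"""Stress-network eigenimage decomposition of regional perfusion matrices.

The stress-stage participant x region rCBF matrix is row-centred (the mean
rCBF across all regions is subtracted per participant, removing global
perfusion) and factorised with an economy-size SVD,

    X_stress,ctrd = U S V^T .

Columns of ``V`` are eigenimages — region-loading patterns of one neural
network — and columns of ``U`` are the per-participant network activity
scores during stress.  Rest-stage activity of the *same* networks is
obtained by projecting the row-centred rest matrix through the stress
decomposition with the Moore-Penrose pseudoinverse,

    U*_rest = X_rest,ctrd (S V^T)^+ ,

and differential (stress-evoked) network activity is ``dU = U - U*_rest``.
Regions are grouped into networks with a winner-takes-all rule on the
absolute loadings of ``V``.

Component scores are the columns of ``U`` (not ``U S``): this is the only
convention under which the projection formula returns rest scores
commensurate with the stress scores (identical Rest and Stress inputs give
``U*_rest == U`` exactly).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "row_center",
    "svd_decompose",
    "explained_variance",
    "project_rest",
    "differential_activity",
    "assign_regions",
    "StressNetworkSVD",
]


def row_center(X):
    """Subtract each row's mean (global perfusion removal per participant).

    Accepts an array or DataFrame; returns the same type.  A matrix whose
    rows already average to zero is returned unchanged with a warning.
    """
    values = np.asarray(X, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D participant x region matrix")
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix contains non-finite entries")
    row_means = values.mean(axis=1, keepdims=True)
    scale = max(np.abs(values).max(), 1.0)
    if np.all(np.abs(row_means) < 1e-10 * scale):
        warnings.warn("matrix appears already row-centred; returning as is")
        return X.copy() if isinstance(X, pd.DataFrame) else values.copy()
    centred = values - row_means
    if isinstance(X, pd.DataFrame):
        return pd.DataFrame(centred, index=X.index, columns=X.columns)
    return centred


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # deterministic orientation: the largest-|loading| region of each
    # component gets a positive loading
    for c in range(V.shape[1]):
        r = np.argmax(np.abs(V[:, c]))
        if V[r, c] < 0:
            V[:, c] = -V[:, c]
            U[:, c] = -U[:, c]
    return U, V


def svd_decompose(X_ctrd) -> "StressNetworkSVD":
    """Economy-size SVD of a centred matrix, returned as a fitted estimator."""
    est = StressNetworkSVD(center=False)
    return est.fit(X_ctrd)


def explained_variance(S) -> np.ndarray:
    """Per-component fraction of input variance, ``S_i^2 / sum S_j^2``."""
    S = np.asarray(S, dtype=float)
    total = np.sum(S**2)
    if total == 0:
        raise ValueError("all singular values are zero; fractions undefined")
    return S**2 / total


def project_rest(X_rest_ctrd, decomposition: "StressNetworkSVD") -> np.ndarray:
    """Rest-stage component scores through the stress decomposition."""
    return decomposition.transform(X_rest_ctrd, center=False)


def differential_activity(U_stress, U_rest_projected) -> np.ndarray:
    """Elementwise stress-minus-rest difference of component scores."""
    U_stress = np.asarray(U_stress, dtype=float)
    U_rest_projected = np.asarray(U_rest_projected, dtype=float)
    if U_stress.shape != U_rest_projected.shape:
        raise ValueError(
            f"shape mismatch: {U_stress.shape} vs {U_rest_projected.shape}"
        )
    return U_stress - U_rest_projected


def assign_regions(V) -> np.ndarray:
    """Winner-takes-all network assignment from the loading matrix.

    Region ``r`` is assigned to the component where ``|V[r, c]|`` is
    maximal; ties break to the lowest component index (numpy argmax).
    """
    V = np.asarray(V, dtype=float)
    return np.argmax(np.abs(V), axis=1)


class StressNetworkSVD(BaseEstimator, TransformerMixin):
    """SVD eigenimage model of stress-stage regional activity.

    ``fit`` takes the stress-stage participant x region rCBF matrix
    (row-centring it unless ``center=False``), stores the factors and the
    winner-takes-all region assignment.  ``transform`` projects a matrix
    from another condition (Rest) through the fitted decomposition,
    returning component scores commensurate with ``scores_``.

    Parameters
    ----------
    center : bool, default True
        Row-centre inputs inside ``fit`` and ``transform``.
    rcond : float or None
        Pseudoinverse truncation tolerance relative to the largest singular
        value; ``None`` uses ``max(n, p) * machine epsilon`` (standard).

    Attributes
    ----------
    scores_ : (n_participants, k) ndarray — columns of U, stress-stage
        network activity per participant.
    singular_values_ : (k,) ndarray, descending.
    components_ : (k, n_regions) ndarray — rows are eigenimages (V^T).
    explained_variance_ratio_ : (k,) ndarray summing to 1.
    assignment_ : (n_regions,) int ndarray — winner-takes-all network of
        each region.
    region_names_, participant_ids_ : labels when fitted from a DataFrame.
    """

    def __init__(self, center: bool = True, rcond: float | None = None):
        self.center = center
        self.rcond = rcond

    def _prepare(self, X, center: bool) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
        if values.ndim != 2:
            raise ValueError("expected a 2-D matrix")
        if not np.all(np.isfinite(values)):
            raise ValueError("matrix contains non-finite entries")
        if center:
            values = values - values.mean(axis=1, keepdims=True)
        return values

    def fit(self, X, y=None):
        values = self._prepare(X, self.center)
        if isinstance(X, pd.DataFrame):
            self.region_names_ = np.asarray(X.columns, dtype=object)
            self.participant_ids_ = np.asarray(X.index, dtype=object)
        else:
            self.region_names_ = None
            self.participant_ids_ = None
        U, S, Vt = np.linalg.svd(values, full_matrices=False)
        V = Vt.T
        U, V = _fix_signs(U, V)
        self.scores_ = U
        self.singular_values_ = S
        self.components_ = V.T
        self.n_components_ = S.size
        self.explained_variance_ratio_ = explained_variance(S)
        self.assignment_ = assign_regions(V)
        self.n_features_in_ = values.shape[1]
        return self

    def transform(self, X, center: bool | None = None) -> np.ndarray:
        """Project a centred (or to-be-centred) matrix onto the networks.

        Implements ``X (S V^T)^+``; for singular values above the
        truncation tolerance this equals ``X V diag(1/S)``.
        """
        if center is None:
            center = self.center
        values = self._prepare(X, center)
        if values.shape[1] != self.n_features_in_:
            raise ValueError(
                f"region mismatch: fitted on {self.n_features_in_} regions, "
                f"got {values.shape[1]}"
            )
        if self.region_names_ is not None and isinstance(X, pd.DataFrame):
            if not np.array_equal(np.asarray(X.columns, dtype=object),
                                  self.region_names_):
                raise ValueError("region labels differ from the fitted matrix")
        S = self.singular_values_
        V = self.components_.T
        n, p = self.scores_.shape[0], self.n_features_in_
        eps = np.finfo(float).eps
        rcond = self.rcond if self.rcond is not None else max(n, p) * eps
        tol = rcond * (S[0] if S.size else 0.0)
        inv_s = np.where(S > tol, 1.0 / np.where(S > tol, S, 1.0), 0.0)
        return values @ V * inv_s

    def differential_activity(self, X_rest) -> np.ndarray:
        """dU = stress scores minus projected rest scores."""
        return differential_activity(self.scores_, self.transform(X_rest))
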