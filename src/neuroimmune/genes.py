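"""Summary marker of T-cell glucocorticoid (GC) signalling.

Eight delta-CT markers — GR, FKBP4, FKBP5 and GILZ measured in CD4+ and
CD8+ T cells — are reduced to one summary score.  Delta-CT is defined as
the geometric mean of housekeeping-gene CT values minus the CT of the gene
of interest, so higher values mean more expression.  The eight markers are
column-centred (per-marker mean removal, no variance scaling) and
factorised with SVD; the first component's participant scores serve as the
single summary measure.  The component sign is oriented so that its
correlation with a reference marker (CD8+ GILZ by default) is
non-negative, making the orientation deterministic across runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

MARKER_COLUMNS = (
    "CD4_GR", "CD4_FKBP4", "CD4_FKBP5", "CD4_GILZ",
    "CD8_GR", "CD8_FKBP4", "CD8_FKBP5", "CD8_GILZ",
)

__all__ = ["delta_ct", "summarize_gc_expression", "GcExpressionSummary",
           "MARKER_COLUMNS"]


def delta_ct(gene_ct, housekeeping_cts) -> float:
    """Delta-CT: geometric mean of housekeeping CTs minus the gene CT."""
    gene_ct = float(gene_ct)
    hk = np.asarray(housekeeping_cts, dtype=float)
    if gene_ct <= 0 or np.any(hk <= 0):
        raise ValueError("CT values must be positive (geometric mean undefined)")
    return float(stats.gmean(hk) - gene_ct)


class GcExpressionSummary(BaseEstimator, TransformerMixin):
    """First-component SVD summary of the eight GC-signalling markers.

    Parameters
    ----------
    reference_marker : str, default "CD8_GILZ"
        Marker whose correlation with the summary is forced non-negative.

    Attributes
    ----------
    loadings_ : (8,) ndarray — first right-singular vector, oriented.
    explained_variance_ratio_ : (8,) ndarray over all components.
    marker_correlations_ : Series — Pearson r between the summary score and
        each raw marker (the similarity profile).
    scores_ : Series of per-participant summary scores from ``fit``.
    mean_ : per-marker means removed before the SVD.
    """

    def __init__(self, reference_marker: str = "CD8_GILZ"):
        self.reference_marker = reference_marker

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if X.shape[1] != 8:
            raise ValueError(f"expected 8 marker columns, got {X.shape[1]}")
        if X.shape[0] < 4:
            raise ValueError("need at least 4 participants")
        values = X.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("markers contain non-finite values")
        if np.any(values.std(axis=0) == 0):
            raise ValueError("zero-variance marker column")
        if self.reference_marker not in X.columns:
            raise ValueError(
                f"reference marker {self.reference_marker!r} not among columns"
            )
        self.mean_ = values.mean(axis=0)
        centred = values - self.mean_
        U, S, Vt = np.linalg.svd(centred, full_matrices=False)
        scores = U[:, 0] * S[0]
        ref = values[:, list(X.columns).index(self.reference_marker)]
        if np.corrcoef(scores, ref)[0, 1] < 0:
            scores = -scores
            Vt[0] = -Vt[0]
        self.loadings_ = Vt[0]
        self.components_ = Vt
        self.singular_values_ = S
        self.explained_variance_ratio_ = S**2 / np.sum(S**2)
        self.marker_correlations_ = pd.Series(
            [np.corrcoef(scores, values[:, j])[0, 1] for j in range(8)],
            index=X.columns, name="r",
        )
        self.scores_ = pd.Series(scores, index=X.index, name="gc_summary")
        self.feature_names_in_ = np.asarray(list(X.columns), dtype=object)
        self.n_features_in_ = 8
        return self

    def transform(self, X) -> np.ndarray:
        """Summary scores for new participants on the fitted component."""
        X = pd.DataFrame(X)
        values = X.to_numpy(dtype=float)
        return (values - self.mean_) @ self.loadings_


def summarize_gc_expression(
    markers: pd.DataFrame, reference_marker: str = "CD8_GILZ"
) -> GcExpressionSummary:
    """Fit the GC summary model on an outlier-filtered marker table."""
    return GcExpressionSummary(reference_marker=reference_marker).fit(markers)
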