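"""Quality control and descriptive group statistics.

Outlier exclusion uses Tukey fences: values more extreme than
``Q1 - k*IQR`` or ``Q3 + k*IQR`` (default multiplier ``k = 1.5``) are
flagged and the participant is dropped from the affected analysis.
Framewise displacement (FWD) is screened once per fMRI condition; each of
the eight gene-expression markers is screened separately and a participant
enters the gene analyses only with non-outlier values on all eight.

Descriptive group comparisons (the cohort table) use the pooled-variance
two-sample t-test computed from summary statistics and the Pearson
chi-square test without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "iqr_fences",
    "flag_outliers",
    "two_sample_t",
    "chi_square_2x2",
    "IqrOutlierFilter",
    "QcReport",
    "run_qc",
]


class InsufficientDataError(ValueError):
    """Raised when fewer than four finite values are available for fences."""


def _quartiles(values: np.ndarray, convention: str) -> tuple[float, float]:
    if convention == "linear":
        q1, q3 = np.percentile(values, [25, 75], method="linear")
    elif convention == "nearest":
        q1, q3 = np.percentile(values, [25, 75], method="nearest")
    else:
        raise ValueError(f"unknown quartile convention {convention!r}")
    return float(q1), float(q3)


def iqr_fences(
    values, multiplier: float = 1.5, convention: str = "linear"
) -> tuple[float, float]:
    """Tukey fences ``(Q1 - m*IQR, Q3 + m*IQR)`` of a numeric vector.

    Quartiles use linear interpolation between order statistics by default;
    the convention is configurable because the fences depend on it.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 4:
        raise InsufficientDataError(
            f"need >= 4 finite values to estimate quartile fences, got {arr.size}"
        )
    q1, q3 = _quartiles(arr, convention)
    iqr = q3 - q1
    return q1 - multiplier * iqr, q3 + multiplier * iqr


def flag_outliers(
    values, multiplier: float = 1.5, convention: str = "linear", strict: bool = True
) -> np.ndarray:
    """Boolean mask, True where a value lies outside the IQR fences.

    With ``strict=True`` (default) only values strictly beyond a fence are
    flagged, so boundary values are retained.  Non-finite values are flagged.
    """
    arr = np.asarray(values, dtype=float)
    lo, hi = iqr_fences(arr, multiplier=multiplier, convention=convention)
    if strict:
        mask = (arr < lo) | (arr > hi)
    else:
        mask = (arr <= lo) | (arr >= hi)
    return mask | ~np.isfinite(arr)


class IqrOutlierFilter(BaseEstimator, TransformerMixin):
    """Column-wise IQR-fence outlier screen in estimator form.

    ``fit`` learns per-column fences; ``transform`` drops rows that are an
    outlier in any column.  ``get_support`` exposes the row mask so callers
    can intersect retained sets across analyses.

    Parameters
    ----------
    multiplier : float, default 1.5
        Fence multiplier ``m`` in ``Q1 - m*IQR`` / ``Q3 + m*IQR``.
    convention : {"linear", "nearest"}, default "linear"
        Quartile estimator.
    strict : bool, default True
        Flag only values strictly beyond a fence.
    """

    def __init__(self, multiplier: float = 1.5, convention: str = "linear",
                 strict: bool = True):
        self.multiplier = multiplier
        self.convention = convention
        self.strict = strict

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        fences = {}
        for col in X.columns:
            fences[col] = iqr_fences(
                X[col].to_numpy(), multiplier=self.multiplier,
                convention=self.convention,
            )
        self.fences_ = fences
        self.feature_names_in_ = np.asarray(list(X.columns), dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def _mask(self, X: pd.DataFrame) -> np.ndarray:
        flagged = np.zeros(len(X), dtype=bool)
        for col, (lo, hi) in self.fences_.items():
            v = X[col].to_numpy(dtype=float)
            if self.strict:
                bad = (v < lo) | (v > hi)
            else:
                bad = (v <= lo) | (v >= hi)
            flagged |= bad | ~np.isfinite(v)
        return flagged

    def get_support(self, X) -> np.ndarray:
        """Row mask, True for rows retained (non-outlier in every column)."""
        return ~self._mask(pd.DataFrame(X))

    def transform(self, X):
        X = pd.DataFrame(X)
        return X.loc[~self._mask(X)]


def two_sample_t(mean1, sd1, n1, mean2, sd2, n2) -> tuple[float, int, float]:
    """Pooled-variance Student t-test from group summary statistics.

    Returns ``(t, df, p)`` with ``df = n1 + n2 - 2`` and a two-sided p-value.
    This is the test behind the cohort descriptive table; it reproduces the
    printed statistics from printed means/SDs/Ns.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0 and mean1 != mean2:
        raise ValueError("zero variance with unequal means is degenerate")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=True
    )
    return float(res.statistic), int(n1 + n2 - 2), float(res.pvalue)


def chi_square_2x2(table) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 count table, no continuity correction."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("degenerate table: zero row or column margin")
    chi2, p, dof, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), int(dof), float(p)


@dataclass
class QcReport:
    """Fences, flagged ids and retained id lists per analysis arm."""

    fences: dict[str, tuple[float, float]] = field(default_factory=dict)
    flagged: dict[str, list] = field(default_factory=dict)
    retained_fmri: list = field(default_factory=list)
    retained_gene: list = field(default_factory=list)
    retained_joint: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "fences": {k: list(v) for k, v in self.fences.items()},
            "flagged": {k: list(v) for k, v in self.flagged.items()},
            "retained_fmri": list(self.retained_fmri),
            "retained_gene": list(self.retained_gene),
            "retained_joint": list(self.retained_joint),
        }


def run_qc(
    fwd: pd.DataFrame,
    markers: pd.DataFrame,
    multiplier: float = 1.5,
    convention: str = "linear",
) -> QcReport:
    """Apply the IQR fence screens and assemble per-analysis retained sets.

    Parameters
    ----------
    fwd : DataFrame indexed by participant id with one framewise-displacement
        column per fMRI condition (e.g. ``fwd_rest``, ``fwd_stress``).
    markers : DataFrame indexed by participant id with the eight delta-CT
        marker columns.

    A participant survives the fMRI gate if non-outlier on FWD in every
    condition, and the gene gate if non-outlier on all eight markers; the
    joint set is the intersection.
    """
    report = QcReport()

    fmri_keep = pd.Series(True, index=fwd.index)
    for col in fwd.columns:
        mask = flag_outliers(fwd[col].to_numpy(), multiplier, convention)
        report.fences[col] = iqr_fences(fwd[col].to_numpy(), multiplier, convention)
        report.flagged[col] = list(fwd.index[mask])
        fmri_keep &= ~mask

    gene_keep = pd.Series(True, index=markers.index)
    for col in markers.columns:
        mask = flag_outliers(markers[col].to_numpy(), multiplier, convention)
        report.fences[col] = iqr_fences(markers[col].to_numpy(), multiplier, convention)
        report.flagged[col] = list(markers.index[mask])
        gene_keep &= ~mask

    report.retained_fmri = list(fwd.index[fmri_keep])
    report.retained_gene = list(markers.index[gene_keep])
    joint = [pid for pid in report.retained_fmri if pid in set(report.retained_gene)]
    report.retained_joint = joint
    return report
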