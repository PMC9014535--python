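"""Associations between network activity, GC gene expression and severity.

Four severity outcomes are modelled in patients with robust permutation
regressions: grey-matter fraction, T2 lesion load (log-transformed voxel
count), clinical disability (EDSS) and information-processing speed
(SDMT).  The covariate of interest is either the differential activity of
the network selected by the brain-immune interaction battery, or the GC
gene-expression summary marker; nuisance covariates are disease duration,
sex, age, task load (brain models only), depression (BDI) and a constant.
Each outcome is tested at an uncorrected two-sided alpha of 0.05 — each
model has a single a-priori covariate of interest.

The relative clinical importance of the selected network is estimated by
refitting the severity model once per network and ranking all networks by
the absolute robust t-statistic of their activity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inference import PermutationResult, robust_fit, robust_permutation_wald

__all__ = [
    "log_lesion_load",
    "severity_design",
    "severity_association",
    "rank_networks",
    "gene_severity_association",
    "SEVERITY_OUTCOMES",
]

SEVERITY_OUTCOMES = ("gm_fraction", "log_lesion", "edss", "sdmt")


def log_lesion_load(lesion_voxels):
    """Natural log of (voxel count + 0.001), the skew-correcting transform."""
    arr = np.asarray(lesion_voxels, dtype=float)
    if np.any(arr < 0):
        raise ValueError("lesion voxel counts must be non-negative")
    return np.log(arr + 0.001)


def _code_covariates(covariates: pd.DataFrame, include_task_load: bool) -> pd.DataFrame:
    cni = pd.DataFrame(index=covariates.index)
    cni["disease_duration"] = covariates["disease_duration"].astype(float)
    cni["sex"] = (covariates["sex"] == "f").astype(float)
    cni["age"] = covariates["age"].astype(float)
    if include_task_load:
        cni["task_load"] = covariates["task_load"].astype(float)
    cni["bdi"] = covariates["bdi"].astype(float)
    cni["const"] = 1.0
    return cni


def severity_design(
    ci_values: pd.Series, covariates: pd.DataFrame, include_task_load: bool = True
) -> pd.DataFrame:
    """Design with the CI as first column followed by the nuisance set."""
    cni = _code_covariates(covariates.loc[ci_values.index], include_task_load)
    design = pd.concat([ci_values.rename("ci"), cni], axis=1)
    return design


def _outcome_vector(severity: pd.DataFrame, outcome: str) -> pd.Series:
    if outcome == "log_lesion":
        return pd.Series(log_lesion_load(severity["lesion_voxels"]),
                         index=severity.index, name="log_lesion")
    return severity[outcome].astype(float)


def severity_association(
    activity: pd.Series,
    outcome: str,
    severity: pd.DataFrame,
    covariates: pd.DataFrame,
    n_permutations: int = 1000,
    seed=None,
) -> PermutationResult:
    """Robust permutation test of one network's activity on one outcome.

    ``activity`` holds the selected network's differential activity for the
    patients to analyse; rows are aligned on its index.
    """
    ids = activity.index.intersection(severity.index)
    y = _outcome_vector(severity.loc[ids], outcome)
    design = severity_design(activity.loc[ids], covariates, include_task_load=True)
    res = robust_permutation_wald(
        y.to_numpy(), design.to_numpy(), ci_columns=[0],
        n_permutations=n_permutations, seed=seed,
    )
    res.name = f"{outcome}~activity"
    return res


def gene_severity_association(
    gc_summary: pd.Series,
    outcome: str,
    severity: pd.DataFrame,
    covariates: pd.DataFrame,
    n_permutations: int = 1000,
    seed=None,
) -> PermutationResult:
    """Robust permutation test of the GC summary marker on one outcome.

    The nuisance set here excludes task load (sex, age, disease duration,
    depression and a constant only).
    """
    ids = gc_summary.index.intersection(severity.index)
    y = _outcome_vector(severity.loc[ids], outcome)
    design = severity_design(gc_summary.loc[ids], covariates,
                             include_task_load=False)
    res = robust_permutation_wald(
        y.to_numpy(), design.to_numpy(), ci_columns=[0],
        n_permutations=n_permutations, seed=seed,
    )
    res.name = f"{outcome}~gc_summary"
    return res


def rank_networks(
    delta_u: pd.DataFrame,
    outcome: str,
    severity: pd.DataFrame,
    covariates: pd.DataFrame,
    selected: int | None = None,
) -> pd.DataFrame:
    """Rank all networks by |t| of their activity in the severity model.

    Fits the robust severity model once per component (no permutations —
    the ranking uses the observed t-statistics only) and sorts descending
    by absolute t.  Returns a DataFrame with columns ``component``,
    ``abs_t``, ``t`` and ``rank`` (1 = closest association); a failed fit
    ranks last.  If ``selected`` is given its rank is stored in
    ``df.attrs["selected_rank"]``.
    """
    ids = delta_u.index.intersection(severity.index)
    y = _outcome_vector(severity.loc[ids], outcome).to_numpy()
    rows = []
    for comp in range(delta_u.shape[1]):
        act = delta_u.iloc[:, comp].loc[ids]
        design = severity_design(act, covariates, include_task_load=True)
        try:
            fit = robust_fit(y, design.to_numpy())
            t = float(fit.t[0])
        except (ValueError, np.linalg.LinAlgError):
            t = np.nan
        rows.append({"component": comp, "t": t,
                     "abs_t": abs(t) if np.isfinite(t) else -np.inf})
    df = pd.DataFrame(rows).sort_values("abs_t", ascending=False,
                                        kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df.loc[~np.isfinite(df["abs_t"]), "abs_t"] = np.nan
    if selected is not None:
        df.attrs["selected_rank"] = int(df.loc[df["component"] == selected,
                                               "rank"].iloc[0])
    return df
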