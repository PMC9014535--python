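"""Synthetic cohorts with the statistical structure the analysis assumes.

No participant-level data from the original study are available, so every
downstream stage is exercised on simulated cohorts that emulate its design:

- participant x region rCBF matrices for a Rest and a Stress stage sharing
  one planted low-rank loading structure, with per-participant global
  perfusion offsets (so row-centring is meaningful) and Gaussian noise;
  latent network scores differ between stages by a per-subject stress
  shift, whose component along one designated network is the planted
  differential activity;
- an eight-marker delta-CT table dominated by a single shared latent
  factor; in patients only, that factor is coupled to the planted
  differential activity with a group-specific (interaction) effect;
- severity outcomes (lesion load, EDSS, SDMT) linearly coupled to the same
  differential activity in patients, grey-matter fraction left uncoupled;
- demographic covariates drawn around the study cohort's descriptive
  statistics, and framewise-displacement scores per condition;
- an optional fraction of participants given FWD or delta-CT values
  offset by ten IQRs, guaranteeing detection by the fence rule.

Group sizes default to the joint-analysis sample (26 patients, 18
controls).  Generation is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genes import MARKER_COLUMNS

__all__ = ["CohortSpec", "SyntheticCohort", "generate_cohort"]

# delta-CT marker population means and loadings on the shared GC factor;
# GILZ loads highest and FKBP4 lowest, mirroring the similarity profile of
# the summary marker
_MARKER_MEANS = np.array([1.5, -2.0, 0.5, 3.0, 1.0, -2.5, 0.8, 3.2])
_MARKER_LOADINGS = np.array([0.60, 0.15, 0.45, 0.80, 0.55, 0.10, 0.60, 0.90])


@dataclass
class CohortSpec:
    """Parameters of one simulated cohort.

    ``interaction_beta`` is the standardized group x differential-activity
    effect on the latent expression factor (patients only);
    ``severity_beta`` the standardized effect of the planted network's
    differential activity on lesion load and EDSS (+) and SDMT (-) in
    patients.  ``noise_sd`` scales the rCBF residual (ml/100 g/min); the
    marker residual is ``noise_sd / 3`` on the delta-CT scale.
    """

    n_patients: int = 26
    n_controls: int = 18
    n_regions: int = 120
    n_networks_true: int = 5
    interaction_network: int = 0
    interaction_beta: float = -0.76
    severity_beta: float = 0.43
    noise_sd: float = 1.0
    outlier_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_patients", "n_controls", "n_regions", "n_networks_true"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.interaction_network < self.n_networks_true:
            raise ValueError("interaction_network must index a planted network")
        if not 0 <= self.outlier_rate < 1:
            raise ValueError("outlier_rate must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SyntheticCohort:
    """All generated tables plus the ground truth used to plant them."""

    rcbf_rest: pd.DataFrame
    rcbf_stress: pd.DataFrame
    markers: pd.DataFrame
    covariates: pd.DataFrame
    severity: pd.DataFrame
    fwd: pd.DataFrame
    truth: dict = field(default_factory=dict)

    @property
    def participants(self) -> pd.Index:
        return self.covariates.index

    def write_tsv(self, outdir) -> dict[str, Path]:
        """Write the six tables as TSV files; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("rcbf_rest", "rcbf_stress", "markers", "covariates",
                     "severity", "fwd"):
            path = outdir / f"{name}.tsv"
            getattr(self, name).to_csv(path, sep="\t", index_label="participant")
            paths[name] = path
        return paths


def _orthonormal_loadings(rng, p, k):
    Q, R = np.linalg.qr(rng.standard_normal((p, k)))
    return Q * np.sign(np.diag(R))  # deterministic orientation


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw one cohort under ``spec``.  See the module docstring for the model."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients + spec.n_controls
    k = spec.n_networks_true
    group = np.concatenate([np.ones(spec.n_patients), np.zeros(spec.n_controls)])
    ids = [f"MS{i + 1:03d}" for i in range(spec.n_patients)] + \
          [f"HP{i + 1:03d}" for i in range(spec.n_controls)]
    regions = [f"R{j + 1:03d}" for j in range(spec.n_regions)]

    # --- brain matrices ----------------------------------------------------
    # spectrum tuned so the leading network explains just under half of the
    # regional variance and networks stay well separated from the noise floor
    W = _orthonormal_loadings(rng, spec.n_regions, k)
    scales = 12.0 * 0.6 ** np.arange(k)
    z_stress = rng.standard_normal((n, k)) * scales
    shift = (0.5 + 0.5 * rng.standard_normal((n, k))) * scales  # stress shift
    z_rest = z_stress - shift
    global_perf = 55.0 + 6.0 * rng.standard_normal(n)
    noise = spec.noise_sd
    rcbf_stress = (global_perf[:, None]
                   + z_stress @ W.T
                   + noise * rng.standard_normal((n, spec.n_regions)))
    rcbf_rest = (global_perf[:, None]
                 + z_rest @ W.T
                 + noise * rng.standard_normal((n, spec.n_regions)))

    j = spec.interaction_network
    d = shift[:, j]  # planted differential activity of the coupled network
    z_d = (d - d.mean()) / d.std(ddof=0)

    # --- gene markers ------------------------------------------------------
    # unit-variance latent factor carrying the planted standardized
    # group x differential-activity interaction effect
    x_int = group * z_d
    sd_int = x_int.std(ddof=0)
    if sd_int > 0 and spec.interaction_beta != 0:
        b = spec.interaction_beta
        latent = (b * x_int / sd_int
                  + np.sqrt(max(0.0, 1.0 - b**2)) * rng.standard_normal(n))
    else:
        latent = rng.standard_normal(n)
    marker_noise = noise / 3.0
    markers = (_MARKER_MEANS[None, :]
               + latent[:, None] * _MARKER_LOADINGS[None, :]
               + marker_noise * rng.standard_normal((n, 8)))

    # --- covariates --------------------------------------------------------
    age = np.where(group == 1,
                   rng.normal(47.12, 11.85, n),
                   rng.normal(42.10, 17.06, n)).clip(18, 75).round(1)
    sex = np.where(rng.random(n) < np.where(group == 1, 25 / 39, 17 / 25),
                   "f", "m")
    duration = np.where(group == 1,
                        np.abs(rng.normal(14.0, 9.0, n)) + 0.5, 0.0).round(1)
    bdi = np.where(group == 1,
                   np.abs(rng.normal(9.82, 7.47, n)),
                   np.abs(rng.normal(2.84, 2.32, n))).round(0)
    task_load = rng.standard_normal(n).round(3)
    covariates = pd.DataFrame(
        {"group": np.where(group == 1, "MS", "HP"), "sex": sex, "age": age,
         "disease_duration": duration, "bdi": bdi, "task_load": task_load},
        index=pd.Index(ids, name="participant"),
    )

    # --- severity (patients) ----------------------------------------------
    sb = spec.severity_beta
    resid_sd = np.sqrt(max(0.0, 1.0 - sb**2))
    z_pat = z_d[group == 1]
    n_pat = spec.n_patients
    true_betas = {"gm_fraction": 0.0, "log_lesion": sb, "edss": sb, "sdmt": -sb}
    lesion_y = sb * z_pat + resid_sd * rng.standard_normal(n_pat)
    edss_y = sb * z_pat + resid_sd * rng.standard_normal(n_pat)
    sdmt_y = -sb * z_pat + resid_sd * rng.standard_normal(n_pat)
    severity = pd.DataFrame(
        {
            "gm_fraction": (0.40 + 0.05 * rng.standard_normal(n_pat))
            .clip(0.25, 0.55).round(4),
            "lesion_voxels": np.round(np.exp(5.5 + 1.1 * lesion_y)).astype(int),
            "edss": (np.round(2 * (3.0 + 1.2 * edss_y)) / 2).clip(0, 9.5),
            "sdmt": np.round(54 + 9.9 * sdmt_y).clip(0, 110).astype(int),
        },
        index=pd.Index(ids[:n_pat], name="participant"),
    )

    # --- framewise displacement -------------------------------------------
    fwd = pd.DataFrame(
        {"fwd_rest": np.abs(rng.normal(0.12, 0.04, n)) + 0.02,
         "fwd_stress": np.abs(rng.normal(0.12, 0.04, n)) + 0.02},
        index=pd.Index(ids, name="participant"),
    ).round(4)

    # --- outlier injection -------------------------------------------------
    n_out = int(round(spec.outlier_rate * n))
    outlier_ids: list[str] = []
    if n_out:
        chosen = rng.choice(n, size=n_out, replace=False)
        for m, row in enumerate(chosen):
            pid = ids[row]
            outlier_ids.append(pid)
            if m % 2 == 0:
                col = "fwd_stress"
                q1, q3 = np.percentile(fwd[col], [25, 75])
                fwd.loc[pid, col] += 10.0 * (q3 - q1)
            else:
                col = MARKER_COLUMNS[int(rng.integers(0, 8))]
                q1, q3 = np.percentile(markers[:, MARKER_COLUMNS.index(col)],
                                       [25, 75])
                markers[row, MARKER_COLUMNS.index(col)] += 10.0 * (q3 - q1)

    marker_df = pd.DataFrame(markers, index=pd.Index(ids, name="participant"),
                             columns=list(MARKER_COLUMNS)).round(4)

    truth = {
        "spec": asdict(spec),
        "loadings": W,
        "z_stress": z_stress,
        "z_rest": z_rest,
        "shift": shift,
        "planted_differential": d,
        "planted_differential_z": z_d,
        "latent_expression": latent,
        "true_severity_betas": true_betas,
        "outlier_ids": outlier_ids,
    }
    return SyntheticCohort(
        rcbf_rest=pd.DataFrame(rcbf_rest, index=pd.Index(ids, name="participant"),
                               columns=regions),
        rcbf_stress=pd.DataFrame(rcbf_stress,
                                 index=pd.Index(ids, name="participant"),
                                 columns=regions),
        markers=marker_df,
        covariates=covariates,
        severity=severity,
        fwd=fwd,
        truth=truth,
    )
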