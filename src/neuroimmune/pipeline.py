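"""End-to-end orchestration: QC -> SVD -> genes -> inference -> severity.

The pipeline consumes six TSV tables (covariates, rest/stress rCBF
matrices, delta-CT markers, severity outcomes, per-condition FWD scores),
applies the IQR-fence QC gates, fits the stress-network SVD and the GC
expression summary, runs the two permutation batteries (repeated-measures
LMM per region; robust interaction test per network) and, for the
network(s) surviving the family-wise Bonferroni threshold, the severity
models and the all-network ranking.  All randomness derives from one
top-level seed through named substreams, so a config plus a seed
reproduces every number exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .decomposition import StressNetworkSVD
from .genes import GcExpressionSummary, MARKER_COLUMNS
from .inference import (
    RepeatedMeasuresPermutationLMM,
    RobustPermutationRegressor,
    bonferroni_threshold,
)
from .qc import QcReport, run_qc
from .severity import (
    SEVERITY_OUTCOMES,
    gene_severity_association,
    rank_networks,
    severity_association,
)

__all__ = ["RunConfig", "RunManifest", "PipelineResult", "run_pipeline",
           "load_tables", "interaction_battery", "stress_battery"]


@dataclass
class RunConfig:
    """File locations and analysis parameters of one reproducible run."""

    covariates: str
    rcbf_rest: str
    rcbf_stress: str
    markers: str
    severity: str
    fwd: str
    output_dir: str = "results"
    n_permutations: int = 1000
    alpha: float = 0.05
    seed: int = 0
    fence_multiplier: float = 1.5
    reference_marker: str = "CD8_GILZ"
    quartile_convention: str = "linear"
    stress_battery_permutations: int | None = None  # default: n_permutations

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunManifest:
    """Per-stage sample-size accounting and provenance stamps."""

    seed: int
    config_hash: str
    version: str = __version__
    started: str = ""
    finished: str = ""
    n_total: int = 0
    n_fmri: int = 0
    n_gene: int = 0
    n_joint: int = 0
    n_patients_severity: int = 0
    n_components: int = 0
    fwe_threshold: float = 0.0
    significant_components: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def load_tables(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Read and schema-check the six input tables."""
    tables = {}
    for name in ("covariates", "rcbf_rest", "rcbf_stress", "markers",
                 "severity", "fwd"):
        path = Path(getattr(config, name))
        if not path.exists():
            raise FileNotFoundError(f"{name} table not found: {path}")
        tables[name] = pd.read_csv(path, sep="\t", index_col="participant")
    cov = tables["covariates"]
    missing = {"group", "sex", "age", "disease_duration", "bdi",
               "task_load"} - set(cov.columns)
    if missing:
        raise ValueError(f"covariates table lacks columns: {sorted(missing)}")
    if cov.index.duplicated().any():
        raise ValueError("duplicated participant ids in covariates")
    if list(tables["markers"].columns) != list(MARKER_COLUMNS):
        raise ValueError("marker table must have the 8 delta-CT columns "
                         f"{MARKER_COLUMNS}")
    if list(tables["rcbf_rest"].columns) != list(tables["rcbf_stress"].columns):
        raise ValueError("rest and stress matrices disagree on region labels")
    return tables


def _group_code(covariates: pd.DataFrame) -> pd.Series:
    return (covariates["group"] == "MS").astype(float)


def interaction_battery(
    delta_u: pd.DataFrame,
    gc_summary: pd.Series,
    covariates: pd.DataFrame,
    n_permutations: int = 1000,
    seed=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Robust group x activity interaction test for every network.

    For each component the GC summary is modelled on the interaction
    regressor (differential activity x group; the CI), the group and
    activity main effects, and the nuisance set (disease duration, sex,
    age, task load, BDI, constant).  Returns one row per component with
    the Bonferroni-corrected significance flag at ``alpha / n_components``.
    """
    ids = delta_u.index.intersection(gc_summary.index)
    cov = covariates.loc[ids]
    y = gc_summary.loc[ids].to_numpy()
    grp = _group_code(cov).to_numpy()
    base = np.column_stack([
        grp,
        cov["disease_duration"].to_numpy(dtype=float),
        (cov["sex"] == "f").to_numpy(dtype=float),
        cov["age"].to_numpy(dtype=float),
        cov["task_load"].to_numpy(dtype=float),
        cov["bdi"].to_numpy(dtype=float),
        np.ones(len(ids)),
    ])
    n_comp = delta_u.shape[1]
    threshold = bonferroni_threshold(alpha, n_comp)
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    child_seeds = ss.generate_state(n_comp) % (2**31)
    rows = []
    for comp in range(n_comp):
        act = delta_u.loc[ids].iloc[:, comp].to_numpy()
        design = np.column_stack([act * grp, act, base])
        est = RobustPermutationRegressor(
            ci=[0], n_permutations=n_permutations,
            seed=int(child_seeds[comp]), fit_intercept=False,
        )
        est.fit(design, y)
        r = est.result_.to_dict()
        r["name"] = f"interaction_c{comp}"
        r["component"] = comp
        r["significant_fwe"] = r["p_value"] < threshold
        rows.append(r)
    out = pd.DataFrame(rows).set_index("component")
    out.attrs["fwe_threshold"] = threshold
    return out


def stress_battery(
    rcbf_rest: pd.DataFrame,
    rcbf_stress: pd.DataFrame,
    covariates: pd.DataFrame,
    n_permutations: int = 1000,
    seed=None,
    regions=None,
) -> pd.DataFrame:
    """Repeated-measures LMM per region: stage, group, stage x group CIs.

    Outcomes are the *uncentred* regional rCBF values of both stages.
    ``regions`` restricts the battery to a subset of region labels.
    """
    ids = rcbf_rest.index.intersection(rcbf_stress.index)
    cov = covariates.loc[ids]
    region_list = list(regions) if regions is not None else list(rcbf_rest.columns)
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    child_seeds = ss.generate_state(len(region_list)) % (2**31)
    grp = _group_code(cov)
    rows = []
    for i, region in enumerate(region_list):
        long = pd.concat([
            pd.DataFrame({
                "participant": ids, "stage": stage_code,
                "rcbf": mat.loc[ids, region].to_numpy(),
                "group": grp.to_numpy(),
                "sex": (cov["sex"] == "f").astype(float).to_numpy(),
                "age": cov["age"].to_numpy(dtype=float),
                "disease_duration": cov["disease_duration"].to_numpy(dtype=float),
                "task_load": cov["task_load"].to_numpy(dtype=float),
                "bdi": cov["bdi"].to_numpy(dtype=float),
            })
            for stage_code, mat in ((0.0, rcbf_rest), (1.0, rcbf_stress))
        ])
        est = RepeatedMeasuresPermutationLMM(
            n_permutations=n_permutations, seed=int(child_seeds[i]))
        est.fit(long, outcome="rcbf",
                cni=("sex", "age", "disease_duration", "task_load", "bdi"))
        for ci_name, res in est.results_.items():
            r = res.to_dict()
            r["region"] = region
            r["ci"] = ci_name
            rows.append(r)
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    """All stage outputs of one run, writable as TSV + JSON sidecars."""

    manifest: RunManifest
    qc_report: QcReport
    decomposition: StressNetworkSVD
    delta_u: pd.DataFrame
    gene_model: GcExpressionSummary
    gc_summary: pd.Series
    stress_results: pd.DataFrame
    interaction_results: pd.DataFrame
    severity_results: pd.DataFrame
    network_ranking: dict[str, pd.DataFrame]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stamp = {"seed": self.manifest.seed,
                 "config_hash": self.manifest.config_hash}
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest.to_dict(), indent=2))
        (outdir / "qc_report.json").write_text(
            json.dumps({**self.qc_report.to_dict(), **stamp}, indent=2))
        dec = self.decomposition
        pd.DataFrame(dec.scores_, index=self.delta_u.index).to_csv(
            outdir / "U_stress.tsv", sep="\t", index_label="participant")
        pd.Series(dec.singular_values_, name="s").to_csv(
            outdir / "S_stress.tsv", sep="\t", index_label="component")
        pd.DataFrame(dec.components_.T, index=dec.region_names_).to_csv(
            outdir / "V_stress.tsv", sep="\t", index_label="region")
        (outdir / "decomposition.json").write_text(json.dumps({
            **stamp,
            "explained_variance_ratio": dec.explained_variance_ratio_.tolist(),
            "assignment": {str(r): int(c) for r, c in
                           zip(dec.region_names_, dec.assignment_)},
            "sign_convention": "largest-|loading| region positive",
        }, indent=2))
        self.delta_u.to_csv(outdir / "delta_U.tsv", sep="\t",
                            index_label="participant")
        self.gc_summary.to_frame().to_csv(outdir / "gc_summary.tsv", sep="\t",
                                          index_label="participant")
        (outdir / "gc_summary.json").write_text(json.dumps({
            **stamp,
            "loadings": dict(zip(self.gene_model.feature_names_in_.tolist(),
                                 self.gene_model.loadings_.tolist())),
            "explained_variance_ratio":
                self.gene_model.explained_variance_ratio_.tolist(),
            "marker_correlations": self.gene_model.marker_correlations_.to_dict(),
        }, indent=2))
        self.stress_results.to_csv(outdir / "stress_battery.tsv", sep="\t",
                                   index=False)
        self.interaction_results.to_csv(outdir / "interaction_battery.tsv",
                                        sep="\t")
        self.severity_results.to_csv(outdir / "severity_results.tsv", sep="\t",
                                     index=False)
        for outcome, ranking in self.network_ranking.items():
            ranking.to_csv(outdir / f"ranking_{outcome}.tsv", sep="\t",
                           index=False)


def run_pipeline(config: RunConfig, tables: dict | None = None,
                 stress_regions=None) -> PipelineResult:
    """Execute every stage and return the collected results.

    ``tables`` may inject in-memory DataFrames (same keys as
    :func:`load_tables`), bypassing file I/O; ``stress_regions`` limits the
    per-region LMM battery.
    """
    started = datetime.now(timezone.utc).isoformat()
    if tables is None:
        tables = load_tables(config)
    cov = tables["covariates"]
    manifest = RunManifest(seed=config.seed, config_hash=config.config_hash(),
                           started=started, n_total=len(cov))

    # -- QC gates -----------------------------------------------------------
    qc_report = run_qc(tables["fwd"], tables["markers"],
                       multiplier=config.fence_multiplier,
                       convention=config.quartile_convention)
    fmri_ids = pd.Index(qc_report.retained_fmri)
    gene_ids = pd.Index(qc_report.retained_gene)
    joint_ids = pd.Index(qc_report.retained_joint)
    manifest.n_fmri = len(fmri_ids)
    manifest.n_gene = len(gene_ids)
    manifest.n_joint = len(joint_ids)
    if len(joint_ids) == 0:
        manifest.finished = datetime.now(timezone.utc).isoformat()
        raise RuntimeError("empty joint complete-case set after QC")

    # -- stress-stage SVD and differential activity -------------------------
    svd = StressNetworkSVD().fit(tables["rcbf_stress"].loc[fmri_ids])
    du = svd.differential_activity(tables["rcbf_rest"].loc[fmri_ids])
    delta_u = pd.DataFrame(du, index=fmri_ids,
                           columns=[f"c{i}" for i in range(svd.n_components_)])
    manifest.n_components = svd.n_components_

    # -- gene summary -------------------------------------------------------
    gene_model = GcExpressionSummary(reference_marker=config.reference_marker)
    gene_model.fit(tables["markers"].loc[gene_ids])
    gc_summary = gene_model.scores_

    # -- LMM stress battery -------------------------------------------------
    b_stress = config.stress_battery_permutations or config.n_permutations
    stress_results = stress_battery(
        tables["rcbf_rest"].loc[fmri_ids], tables["rcbf_stress"].loc[fmri_ids],
        cov, n_permutations=b_stress,
        seed=_stage_seed(config.seed, "stress"), regions=stress_regions)

    # -- robust interaction battery over all networks -----------------------
    interaction_results = interaction_battery(
        delta_u.loc[joint_ids], gc_summary.loc[joint_ids], cov,
        n_permutations=config.n_permutations,
        seed=_stage_seed(config.seed, "interaction"), alpha=config.alpha)
    manifest.fwe_threshold = interaction_results.attrs["fwe_threshold"]
    significant = interaction_results.index[
        interaction_results["significant_fwe"]].tolist()
    manifest.significant_components = significant

    # -- severity models ----------------------------------------------------
    patients = cov.index[cov["group"] == "MS"]
    sev_ids = fmri_ids.intersection(patients).intersection(
        tables["severity"].index)
    manifest.n_patients_severity = len(sev_ids)
    sev_states = (np.random.SeedSequence(_stage_seed(config.seed, "severity"))
                  .generate_state(4 * (manifest.n_components + 1)) % (2**31))
    sev_counter = iter(sev_states.tolist())
    selected = significant or ([int(interaction_results["wald"].idxmax())]
                               if len(interaction_results) else [])
    sev_rows = []
    rankings: dict[str, pd.DataFrame] = {}
    for comp in selected:
        act = delta_u.loc[sev_ids].iloc[:, comp]
        for outcome in SEVERITY_OUTCOMES:
            res = severity_association(
                act, outcome, tables["severity"].loc[sev_ids], cov,
                n_permutations=config.n_permutations,
                seed=int(next(sev_counter)))
            row = res.to_dict()
            row.update(component=comp, ci="activity",
                       selected_by_fwe=comp in significant)
            sev_rows.append(row)
            ranking = rank_networks(delta_u.loc[sev_ids], outcome,
                                    tables["severity"].loc[sev_ids], cov,
                                    selected=comp)
            rankings[f"{outcome}_c{comp}"] = ranking
    gene_sev_ids = gene_ids.intersection(patients).intersection(
        tables["severity"].index)
    for outcome in SEVERITY_OUTCOMES:
        res = gene_severity_association(
            gc_summary.loc[gene_sev_ids], outcome,
            tables["severity"].loc[gene_sev_ids], cov,
            n_permutations=config.n_permutations,
            seed=int(next(sev_counter)))
        row = res.to_dict()
        row.update(component=-1, ci="gc_summary", selected_by_fwe=False)
        sev_rows.append(row)
    severity_results = pd.DataFrame(sev_rows)

    manifest.finished = datetime.now(timezone.utc).isoformat()
    return PipelineResult(
        manifest=manifest, qc_report=qc_report, decomposition=svd,
        delta_u=delta_u, gene_model=gene_model, gc_summary=gc_summary,
        stress_results=stress_results, interaction_results=interaction_results,
        severity_results=severity_results, network_ranking=rankings,
    )
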