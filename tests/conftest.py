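import numpy as np
import pandas as pd
import pytest

from neuroimmune import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default-condition cohort with injected outliers, shared read-only."""
    return generate_cohort(CohortSpec(seed=42, outlier_rate=0.1))


@pytest.fixture(scope="session")
def clean_cohort():
    """Default-condition cohort without outliers."""
    return generate_cohort(CohortSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tables(clean_cohort):
    """In-memory table dict in the pipeline's input layout."""
    c = clean_cohort
    return {
        "covariates": c.covariates,
        "rcbf_rest": c.rcbf_rest,
        "rcbf_stress": c.rcbf_stress,
        "markers": c.markers,
        "severity": c.severity,
        "fwd": c.fwd,
    }


def make_long_repeated(n_subjects, seed=0, stage_effect=0.0, group_effect=0.0,
                       interaction_effect=0.0, subject_sd=2.0, noise_sd=1.0,
                       with_covariates=False):
    """Balanced two-stage long table with known fixed effects."""
    rng = np.random.default_rng(seed)
    subj = np.repeat(np.arange(n_subjects), 2)
    stage = np.tile([0.0, 1.0], n_subjects)
    group = np.repeat(rng.integers(0, 2, n_subjects).astype(float), 2)
    intercepts = np.repeat(rng.normal(0, subject_sd, n_subjects), 2)
    y = (intercepts + stage_effect * stage + group_effect * group
         + interaction_effect * stage * group
         + noise_sd * rng.standard_normal(2 * n_subjects))
    data = {"participant": subj, "stage": stage, "group": group, "y": y}
    if with_covariates:
        data["age"] = np.repeat(rng.normal(45, 10, n_subjects), 2)
    return pd.DataFrame(data)
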