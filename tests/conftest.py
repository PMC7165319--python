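"""Shared fixtures: tiny hand-built matrices and session-scoped synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import uridx
from uridx import synthetic_data as sd
from uridx.io_preprocess import AbundanceMatrix

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_matrix(values, stage="raw_ibaq", proteins=None, samples=None) -> AbundanceMatrix:
    values = np.asarray(values, dtype=float)
    proteins = proteins or [f"PROT{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return AbundanceMatrix(pd.DataFrame(values, index=proteins, columns=samples), stage)


def make_metadata(sample_ids, groups, split="discovery") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "group": list(groups),
            "subgroup": [g if g == "AA" else "CHO" for g in groups],
            "split": split,
            "instrument": "test",
        }
    )


@pytest.fixture(scope="session")
def strong_cohort():
    """A strong-effect synthetic cohort (10 markers, |log2FC| = 2.5, n=30/30)."""
    spec = sd.strong_effect_spec()
    disease, normal, meta, truth = sd.generate_cohort(spec, seed=11)
    return spec, disease, normal, meta, truth


@pytest.fixture(scope="session")
def strong_discovery(strong_cohort):
    """Discovery workflow output on the strong-effect cohort."""
    _, disease, normal, meta, _ = strong_cohort
    return uridx.run_discovery(disease, normal, meta, k=10, seed=3)


@pytest.fixture(scope="session")
def null_cohort():
    """A no-effect cohort: log2 matrix, metadata and the detected-protein index."""
    spec = sd.null_spec()
    disease, normal, meta, truth = sd.generate_cohort(spec, seed=5)
    _, quantile = uridx.normalize_chain(disease)
    log2m = uridx.log2_impute(quantile)
    detected = log2m.data.index[
        (log2m.data.to_numpy() > log2m.imputation_value).any(axis=1)
    ]
    return spec, disease, normal, meta, log2m, detected
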