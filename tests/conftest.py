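"""Shared fixtures: one default synthetic cohort, trained clock and
pipeline run per session (they are the expensive pieces)."""

import warnings

import numpy as np
import pytest
from hypothesis import settings

import folate_response as fr

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from folate_response.pipeline import PipelineConfig, run_pipeline

SEED = 20240901


@pytest.fixture(scope="session")
def dataset():
    """Default study conditions: 21 responders / 22 non-responders."""
    return fr.generate_cohort(fr.SimConfig(seed=SEED))


@pytest.fixture(scope="session")
def labels(dataset):
    return fr.label_cohort(dataset.cohort)


@pytest.fixture(scope="session")
def trained_clock(dataset):
    """Clock trained on the reference beta matrix (CV-selected penalty)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fr.train_filtered_clock(
            dataset.beta_train,
            dataset.train_ages.loc[dataset.beta_train.columns],
            dataset.whitelist,
            seed=SEED,
        )


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full end-to-end pipeline run on the default configuration."""
    outdir = tmp_path_factory.mktemp("pipeline")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = run_pipeline(PipelineConfig(outdir=str(outdir), seed=SEED))
    return report, outdir


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
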