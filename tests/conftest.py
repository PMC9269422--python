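"""Shared fixtures: cohorts are generated once per session (they are the
expensive inputs reused across modules)."""

import numpy as np
import pytest

import skinraman as sr


@pytest.fixture(scope="session")
def default_config():
    return sr.CohortConfig(seed=0)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return sr.generate_cohort(default_config)


@pytest.fixture(scope="session")
def processed_default(default_cohort):
    return sr.preprocess_cohort(default_cohort)


@pytest.fixture(scope="session")
def noiseless_config():
    """All stochastic intensity perturbations off; baseline retained."""
    return sr.CohortConfig(seed=0, noise_sd=0.0, peak_jitter_sd=0.0, subject_scale_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_config):
    return sr.generate_cohort(noiseless_config)


@pytest.fixture(scope="session")
def grid():
    return sr.build_grid(400.0, 1800.0, 1384)


@pytest.fixture(scope="session")
def peaks():
    return sr.load_peak_library()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
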