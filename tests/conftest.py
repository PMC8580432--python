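import numpy as np
import pytest

import pulsewave as pw
from pulsewave import synthetic_ecg as synth


@pytest.fixture(scope="session")
def small_spec() -> pw.CohortSpec:
    return pw.CohortSpec(n_patients=20, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec) -> pw.Cohort:
    return pw.generate_cohort(small_spec)


@pytest.fixture(scope="session")
def cohort_manifest(small_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    return synth.write_cohort(small_cohort, out)


@pytest.fixture(scope="session")
def default_config() -> pw.PipelineConfig:
    return pw.PipelineConfig(seed=7)


@pytest.fixture(scope="session")
def trained_archive(default_config, cohort_manifest, tmp_path_factory):
    out = tmp_path_factory.mktemp("archive")
    result = pw.run_train(default_config, cohort_manifest, out)
    return result


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
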