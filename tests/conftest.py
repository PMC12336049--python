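import warnings

import numpy as np
import pytest

from rri.config import AnalysisConfig, AttritionConfig, GeneratorConfig
from rri.synthetic import generate_cohort


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(seed=1234)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Reduced cohort for fast end-to-end fits."""
    return GeneratorConfig(n_subjects=300, seed=77)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def fast_analysis() -> AnalysisConfig:
    return AnalysisConfig(quadrature_nodes=5)


@pytest.fixture(scope="session")
def small_joint_fit(small_cohort, fast_analysis):
    """One converged joint moderation fit shared across probing tests."""
    from rri.analytical import fit_analytical

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = fit_analytical(small_cohort, config=fast_analysis)
    assert res.fit.converged
    return res


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
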