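import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import balancekit as bk
from balancekit import pipeline

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def template():
    return bk.default_template()


@pytest.fixture(scope="session")
def small_cohort():
    """3 participants per group, both conditions: 36 trials."""
    return bk.generate_cohort(n_per_group=3, seed=42)


@pytest.fixture(scope="session")
def small_results(small_cohort):
    return pipeline.analyze_cohort(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
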