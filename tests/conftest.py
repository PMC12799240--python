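import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gatescan.pipeline import discover_cohort
from gatescan.synthetic_data import generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cohort():
    """The default study cohort: 50 genomes, 10 implants, 10 decoys."""
    return generate_cohort(seed=1)


@pytest.fixture(scope="session")
def default_report(default_cohort):
    return discover_cohort(default_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
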