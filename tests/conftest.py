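import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import breathmap as bm

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bnp37_cohort():
    """The default 37-sample four-class cohort with its ground truth."""
    scenario = bm.default_scenario()
    chromatograms, labels, compounds = bm.generate_cohort(scenario)
    return scenario, chromatograms, labels, compounds


@pytest.fixture(scope="session")
def bnp37_tables(bnp37_cohort):
    _, chromatograms, _, _ = bnp37_cohort
    return bm.detect_cohort(chromatograms)


@pytest.fixture(scope="session")
def bnp37_matrix(bnp37_cohort, bnp37_tables):
    scenario, _, _, _ = bnp37_cohort
    return bm.profile_cohort(
        bnp37_tables, (scenario.rt_start, scenario.rt_end)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20221228)
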