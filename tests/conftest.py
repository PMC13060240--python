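import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from trajalign import CohortConfig, gen_cohort
from trajalign.cohort import firing_rate_spec

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def rate_cohort():
    """4-subject quarterly cohort with one Gaussian firing-rate outcome."""
    spec = dataclasses.replace(firing_rate_spec(), noise_sd=0.75)
    cc = CohortConfig(seed=42, outcome_specs=[spec])
    subjects, ds = gen_cohort(cc)
    return cc, subjects, ds
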