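import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import udlbias as u

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def exp1_obs():
    """Self-paced cohort (10 participants), headings-only fast path."""
    return u.generate_observations("exp1", u.EXP1_DEFAULTS, 10, seed=101)


@pytest.fixture(scope="session")
def exp2_obs():
    """Delayed-response cohort (16+16 participants), headings-only."""
    return u.generate_observations("exp2", u.EXP2_DEFAULTS, 32, seed=102)


@pytest.fixture(scope="session")
def small_rendered():
    """A small fully rendered cohort plus its kinematic reduction."""
    ds = u.generate_dataset("exp1", u.EXP1_DEFAULTS, 2, seed=103)
    obs = u.reduce_dataset(ds)
    return ds, obs
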