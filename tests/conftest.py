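import numpy as np
import pytest

from fcreact.cohort import SimParams, generate_cohort


@pytest.fixture(scope="session")
def tiny_params() -> SimParams:
    """A miniature cohort: fast enough for per-test use, structurally complete."""
    return SimParams(n_resistant=8, n_responsive=8, n_controls=6,
                     n_timepoints=60, n_cortical=12,
                     planted_edge=("ach", 1, 10), seed=123)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_params):
    return generate_cohort(tiny_params)


@pytest.fixture(scope="session")
def default_size_session():
    """One subject-session at the default ROI sizes (96 + 8 + 4), short scan."""
    params = SimParams(n_resistant=2, n_responsive=2, n_controls=0,
                       n_timepoints=30, seed=7)
    _, series = generate_cohort(params)
    return series[0]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
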