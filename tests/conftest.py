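import numpy as np
import pytest

from magest import ObserverParams, TrialCondition


@pytest.fixture(scope="session")
def exp1_conditions():
    from magest import enumerate_design

    return enumerate_design(1)


@pytest.fixture(scope="session")
def exp2_conditions():
    from magest import enumerate_design

    return enumerate_design(2)


@pytest.fixture
def control_condition():
    """A control numerosity trial at the mean level factor's neighbour."""
    return TrialCondition(
        1, "numerosity", 1.05, (("duration", "mean"), ("surface", "mean")), "linear"
    )


@pytest.fixture
def default_params():
    return ObserverParams.default()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def logistic_plus_counts(levels, mu, s, n_per_level, rng):
    """Draw binomial '+' counts from a logistic choice model (shared oracle)."""
    from scipy.special import expit

    levels = np.asarray(levels, dtype=float)
    p = expit((levels - mu) / s)
    return rng.binomial(n_per_level, p)
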