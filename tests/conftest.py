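import numpy as np
import pytest
from hypothesis import settings
from scipy.special import expit

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_scored_outcomes(a, b, n, seed, mu=0.0, sigma=1.5):
    """Minimal miscalibrated scores: p = expit(z), P(y=1) = expit(a + b*z).

    Kept independent of the package's cohort generator so metric tests do
    not depend on the code they help validate.
    """
    rng = np.random.default_rng(seed)
    z = rng.normal(mu, sigma, n)
    p = expit(z)
    y = (rng.random(n) < expit(a + b * z)).astype(float)
    return p, y


@pytest.fixture
def calibrated_sample():
    """Well-calibrated (a, b) = (0, 1) scores with both classes present."""
    return make_scored_outcomes(0.0, 1.0, 5_000, seed=42)


@pytest.fixture
def miscalibrated_sample():
    """Overestimating, underfitted scores of study-like magnitude."""
    return make_scored_outcomes(-1.17, 1.37, 5_000, seed=7)
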