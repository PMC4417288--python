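import numpy as np
import pytest

from lrfdr import MixtureTheta, TestSummary


def draw_summary(
    theta: MixtureTheta,
    n: int,
    seed: int,
    psi: float | np.ndarray = 1.0,
) -> tuple[TestSummary, np.ndarray]:
    """Sample (d_v, o_v) straight from the hierarchical model with known psi."""
    rng = np.random.default_rng(seed)
    psi = np.broadcast_to(np.asarray(psi, dtype=float), (n,))
    o = rng.choice(np.array([-1, 0, 1]), size=n, p=theta.probs)
    mean = o * theta.mu
    var = np.where(o == 0, theta.sigma2, theta.tau2) + psi
    d = rng.normal(mean, np.sqrt(var))
    return TestSummary(d=d, psi=psi.copy()), o


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def theta_onesided():
    """The canonical recovery setting: 20% null, strong positive effects."""
    return MixtureTheta(p0=0.2, p1=0.8, pm1=0.0, mu=3.0, sigma2=0.3, tau2=0.5)


@pytest.fixture
def theta_twosided():
    return MixtureTheta(p0=0.5, p1=0.3, pm1=0.2, mu=2.0, sigma2=0.3, tau2=0.5)
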