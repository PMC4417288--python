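"""Hierarchical two-group mixture model for large-scale testing.

The model: for test (voxel) ``v`` the control group responses are
``y_vj1 = xi_v + e_vj1`` and the case group responses are
``y_vj2 = xi_v + w_v + e_vj2`` with ``e_vjk ~ N(0, phi_vk)``.  Conditional on
the effect ``w_v``, the difference of group means

    d_v = mean(y_v.2) - mean(y_v.1)  ~  N(w_v, psi_v),
    psi_v = phi_v1/n1 + phi_v2/n2,

and a latent three-state label ``o_v`` assigns each test to one of the effect
components

    o_v =  0  ("uninteresting"):  w_v ~ N(0,   sigma2)
    o_v = +1  (positive effect):  w_v ~ N(+mu, tau2)
    o_v = -1  (negative effect):  w_v ~ N(-mu, tau2)

so marginally ``d_v | o_v = s`` is normal with mean ``s*mu`` and variance
``sigma2 + psi_v`` (null) or ``tau2 + psi_v`` (alternative).  The nuisance
mean ``xi_v`` cancels in ``d_v`` and is never estimated; ``psi_v`` is replaced
by the unbiased plug-in from the per-group sample variances.

All densities are evaluated in log space: the intended scale is 1e5-1e6 tests
with extreme tails, where linear-scale densities underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

#: Latent-state column order used by every [N x 3] state array in the package.
STATES = (-1, 0, 1)

#: Default lower bound kept on sigma2 / tau2 so the mixture likelihood stays
#: bounded (a component variance collapsing onto one point inflates the
#: likelihood without bound; a local maximizer in the interior is the target).
DEFAULT_VARIANCE_FLOOR = 1e-8

_PROB_TOL = 1e-12


class ModelError(ValueError):
    """Invalid model input or parameterization."""


@dataclass(frozen=True)
class MixtureTheta:
    """Fixed parameters theta = (p0, p1, p-1, mu, sigma2, tau2).

    ``mu`` is stored nonnegative; the sign of an effect is carried by the
    latent state (state +1 has mean ``+mu``, state -1 mean ``-mu``).  A
    one-sided model simply fixes one of ``p1``/``pm1`` to zero.
    """

    p0: float
    p1: float
    pm1: float = 0.0
    mu: float = 0.0
    sigma2: float = DEFAULT_VARIANCE_FLOOR
    tau2: float = DEFAULT_VARIANCE_FLOOR

    def __post_init__(self) -> None:
        for name in ("p0", "p1", "pm1"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ModelError(f"{name}={p} outside [0, 1]")
        if abs(self.p0 + self.p1 + self.pm1 - 1.0) > _PROB_TOL:
            raise ModelError(
                f"state probabilities sum to {self.p0 + self.p1 + self.pm1}, not 1"
            )
        if self.mu < 0.0:
            raise ModelError(f"mu={self.mu} must be nonnegative (sign lives in the state)")
        if self.sigma2 <= 0.0 or self.tau2 <= 0.0:
            raise ModelError("sigma2 and tau2 must be positive")

    @property
    def probs(self) -> np.ndarray:
        """State probabilities in ``STATES`` order (-1, 0, +1)."""
        return np.array([self.pm1, self.p0, self.p1])

    def component_mean(self, state: int) -> float:
        return state * self.mu

    def component_var(self, state: int) -> float:
        return self.sigma2 if state == 0 else self.tau2


@dataclass(frozen=True)
class GroupedResponses:
    """Raw per-test responses for the control (y1) and case (y2) groups."""

    y1: np.ndarray
    y2: np.ndarray

    def __post_init__(self) -> None:
        y1 = np.asarray(self.y1, dtype=float)
        y2 = np.asarray(self.y2, dtype=float)
        object.__setattr__(self, "y1", y1)
        object.__setattr__(self, "y2", y2)
        if y1.ndim != 2 or y2.ndim != 2:
            raise ModelError("y1 and y2 must be 2-d (tests x subjects)")
        if y1.shape[0] != y2.shape[0]:
            raise ModelError(
                f"groups disagree on the number of tests: {y1.shape[0]} vs {y2.shape[0]}"
            )
        if y1.shape[1] < 2 or y2.shape[1] < 2:
            raise ModelError("need at least 2 subjects per group for sample variances")
        if not (np.isfinite(y1).all() and np.isfinite(y2).all()):
            raise ModelError("missing or non-finite responses are not allowed")

    @property
    def n_tests(self) -> int:
        return self.y1.shape[0]

    @property
    def n1(self) -> int:
        return self.y1.shape[1]

    @property
    def n2(self) -> int:
        return self.y2.shape[1]


@dataclass(frozen=True)
class TestSummary:
    """Per-test mean difference ``d_v`` and plug-in sampling variance ``psi_v``."""

    __test__ = False  # not a pytest class, despite the name

    d: np.ndarray
    psi: np.ndarray

    def __post_init__(self) -> None:
        d = np.atleast_1d(np.asarray(self.d, dtype=float))
        psi = np.atleast_1d(np.asarray(self.psi, dtype=float))
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "psi", psi)
        if d.shape != psi.shape or d.ndim != 1:
            raise ModelError("d and psi must be 1-d vectors of equal length")
        if not (np.isfinite(d).all() and np.isfinite(psi).all()):
            raise ModelError("non-finite values in d or psi")
        if np.any(psi <= 0.0):
            bad = int(np.flatnonzero(psi <= 0.0)[0])
            raise ModelError(f"psi must be positive; test {bad} has psi={psi[bad]}")

    @property
    def n_tests(self) -> int:
        return self.d.size


@dataclass(frozen=True)
class LatentState:
    """True per-test states, available in simulations."""

    o: np.ndarray

    def __post_init__(self) -> None:
        o = np.atleast_1d(np.asarray(self.o, dtype=int))
        object.__setattr__(self, "o", o)
        if not np.isin(o, (-1, 0, 1)).all():
            raise ModelError("latent states must lie in {-1, 0, 1}")


def summarize_groups(g: GroupedResponses) -> TestSummary:
    """Reduce raw group responses to ``(d_v, psi_hat_v)``.

    ``d_v`` is the case-minus-control difference of means and
    ``psi_hat_v = s1_v^2/n1 + s2_v^2/n2`` with unbiased (ddof=1) sample
    variances, the plug-in estimate of the sampling variance of ``d_v``.
    """
    d = g.y2.mean(axis=1) - g.y1.mean(axis=1)
    psi = g.y1.var(axis=1, ddof=1) / g.n1 + g.y2.var(axis=1, ddof=1) / g.n2
    if np.any(psi <= 0.0):
        bad = int(np.flatnonzero(psi <= 0.0)[0])
        raise ModelError(
            f"test {bad} has zero plug-in variance (both groups constant); "
            "cannot form a test statistic"
        )
    return TestSummary(d=d, psi=psi)


def _log_normal_pdf(x: np.ndarray, mean: float, var: np.ndarray | float) -> np.ndarray:
    var = np.asarray(var, dtype=float)
    return -0.5 * (np.log(2.0 * np.pi * var) + (np.asarray(x) - mean) ** 2 / var)


def log_component_density(d, psi, state: int, theta: MixtureTheta) -> np.ndarray:
    """Log density of ``d`` given latent state: N(s*mu, var_s + psi)."""
    if state not in (-1, 0, 1):
        raise ModelError(f"state must be in {{-1,0,1}}, got {state}")
    var = theta.component_var(state) + np.asarray(psi, dtype=float)
    if np.any(var <= 0.0):
        raise ModelError("non-positive component variance")
    return _log_normal_pdf(np.asarray(d, dtype=float), theta.component_mean(state), var)


def component_density(d, psi, state: int, theta: MixtureTheta):
    """Density of ``d`` given latent state (linear scale)."""
    return np.exp(log_component_density(d, psi, state, theta))


def log_state_densities(ts: TestSummary, theta: MixtureTheta) -> np.ndarray:
    """[N x 3] array of ``log(p_s) + log f_s(d_v)`` in STATES order.

    States with zero prior probability get ``-inf`` columns.
    """
    out = np.empty((ts.n_tests, 3))
    for j, s in enumerate(STATES):
        p = theta.probs[j]
        if p > 0.0:
            out[:, j] = np.log(p) + log_component_density(ts.d, ts.psi, s, theta)
        else:
            out[:, j] = -np.inf
    return out


def marginal_loglik(ts: TestSummary, theta: MixtureTheta) -> float:
    """Marginal log-likelihood sum_v log sum_s p_s f_s(d_v; psi_hat_v)."""
    return float(logsumexp(log_state_densities(ts, theta), axis=1).sum())


def log_likelihood_ratios(ts: TestSummary, theta: MixtureTheta) -> tuple[np.ndarray, np.ndarray]:
    """Per-test log of ``R_P = p1 f1 / (p0 f0)`` and ``R_N = pm1 fm1 / (p0 f0)``.

    A direction with zero prior mass yields ``-inf`` (ratio zero).  The
    prior-weighted form makes the ratio directly comparable to the decision
    cost ``alpha``.
    """
    if theta.p0 <= 0.0:
        raise ModelError("likelihood ratios undefined when p0 = 0")
    log_null = np.log(theta.p0) + log_component_density(ts.d, ts.psi, 0, theta)
    if theta.p1 > 0.0:
        log_rp = np.log(theta.p1) + log_component_density(ts.d, ts.psi, 1, theta) - log_null
    else:
        log_rp = np.full(ts.n_tests, -np.inf)
    if theta.pm1 > 0.0:
        log_rn = np.log(theta.pm1) + log_component_density(ts.d, ts.psi, -1, theta) - log_null
    else:
        log_rn = np.full(ts.n_tests, -np.inf)
    return log_rp, log_rn


def likelihood_ratios(ts: TestSummary, theta: MixtureTheta) -> tuple[np.ndarray, np.ndarray]:
    """Linear-scale (R_P, R_N); see :func:`log_likelihood_ratios`."""
    log_rp, log_rn = log_likelihood_ratios(ts, theta)
    with np.errstate(over="ignore"):
        return np.exp(log_rp), np.exp(log_rn)


def responsibilities(ts: TestSummary, theta: MixtureTheta) -> np.ndarray:
    """Posterior state probabilities P(o_v = s | d_v; theta), [N x 3] in STATES order."""
    log_joint = log_state_densities(ts, theta)
    log_norm = logsumexp(log_joint, axis=1, keepdims=True)
    return np.exp(log_joint - log_norm)
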