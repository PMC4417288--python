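"""Optimal likelihood-ratio decision rules with model-based FDR calibration.

With the effect mixture fitted, the decision-theoretic rule that minimizes
false non-discoveries subject to a cost ``alpha`` per false discovery rejects
test ``v`` exactly when the prior-weighted likelihood ratio

    R(d_v) = p_s f_s(d_v) / (p0 f0(d_v)),   s the tested direction,

satisfies ``R >= alpha``.  For each test this rejection set is an explicit
region in ``d``: ``log R`` is quadratic in ``d``, so the region is the
complement of an interval (the usual ``tau2 > sigma2`` case), an interval, or
degenerate.  The expected number of false discoveries of a rule is then the
null-component mass of these regions,

    E_hat(V)(alpha) = sum_v p0 [Phi(cL_v / s0_v) + 1 - Phi(cU_v / s0_v)],

with ``s0_v = sqrt(sigma2 + psi_hat_v)``, and the FDR estimate is
``E_hat(V) / max(D, E_hat(V))`` with ``D`` the realized discovery count (the
``max`` guard keeps the estimate in [0, 1]; the raw ratio is available).
Calibration searches the observed ratios for the smallest ``alpha`` (largest
rejection set) whose estimated FDR stays within the target level ``kappa``.

The two-sided problem takes three actions (declare negative / null /
positive); each direction is calibrated separately, possibly at different
levels, and a rejected test is assigned the direction with the larger ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.stats import norm

from .model import LatentState, MixtureTheta, ModelError, TestSummary, log_likelihood_ratios

Direction = Literal["pos", "neg"]

# region kinds (vectorized codes)
_OUTSIDE, _INSIDE, _ALL, _NONE = 0, 1, 2, 3

_EXACT_SCAN_MAX = 4096  # exhaustive alpha search below this many tests


@dataclass(frozen=True)
class RejectionRegion:
    """Per-test rejection set in ``d``.

    ``inside=False`` (typical, ``tau2 > sigma2``): reject when ``d <= cL`` or
    ``d >= cU``.  ``inside=True`` (``tau2 < sigma2``): reject when
    ``cL <= d <= cU``.  ``empty`` marks a region with no rejections at all;
    ``full`` the always-reject limit (alpha below the ratio's infimum).
    """

    cL: float
    cU: float
    empty: bool = False
    inside: bool = False
    full: bool = False

    def contains(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        if self.full:
            return np.ones(d.shape, dtype=bool)
        if self.empty:
            return np.zeros(d.shape, dtype=bool)
        if self.inside:
            return (d >= self.cL) & (d <= self.cU)
        return (d <= self.cL) | (d >= self.cU)


@dataclass(frozen=True)
class DecisionSet:
    """Actions delta_v in {-1, 0, +1} with the calibrated thresholds."""

    delta: np.ndarray
    kappa: float | tuple[float, float]
    alpha_plus: float | None = None
    alpha_minus: float | None = None
    fdr_hat_plus: float | None = None
    fdr_hat_minus: float | None = None

    @property
    def n_discoveries(self) -> int:
        return int(np.count_nonzero(self.delta))


@dataclass(frozen=True)
class OutcomeCounts:
    """Realized outcome table of N tests: nulls N0, false/true discoveries V/S."""

    N: int
    N0: int
    V: int
    S: int
    D: int

    def __post_init__(self) -> None:
        if self.V + self.S != self.D:
            raise ValueError("V + S must equal D")
        if not (0 <= self.V and 0 <= self.S and self.D <= self.N):
            raise ValueError("inconsistent outcome counts")

    @property
    def fdp(self) -> float:
        """False discovery proportion V/D (0 when nothing is discovered)."""
        return self.V / self.D if self.D else 0.0

    @property
    def fndp(self) -> float:
        """False non-discovery proportion: missed alternatives / non-discoveries."""
        missed = (self.N - self.N0) - self.S
        non_disc = self.N - self.D
        return missed / non_disc if non_disc else 0.0


def _direction_log_prior_ratio(theta: MixtureTheta, direction: Direction) -> float:
    p_dir = theta.p1 if direction == "pos" else theta.pm1
    if theta.p0 <= 0.0:
        raise ModelError("p0 = 0: likelihood ratio undefined")
    if p_dir <= 0.0:
        return -np.inf
    return float(np.log(p_dir / theta.p0))


def _region_arrays(
    theta: MixtureTheta, psi: np.ndarray, log_alpha: float, direction: Direction
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized region solve: (cL, cU, kind) per psi for {log R(d) >= log_alpha}.

    log R(d) = a d^2 + b d + c with
      a = (1/s0^2 - 1/s1^2)/2,  b = m/s1^2,
      c = log(p_dir/p0) + log(s0/s1) - m^2/(2 s1^2),
    s0^2 = sigma2+psi, s1^2 = tau2+psi, m = +-mu.
    """
    psi = np.asarray(psi, dtype=float)
    m = theta.mu if direction == "pos" else -theta.mu
    s0sq = theta.sigma2 + psi
    s1sq = theta.tau2 + psi
    log_prior = _direction_log_prior_ratio(theta, direction)

    cL = np.full(psi.shape, -np.inf)
    cU = np.full(psi.shape, np.inf)
    kind = np.full(psi.shape, _NONE, dtype=np.int8)
    if not np.isfinite(log_prior):  # zero prior mass: never rejects
        return cL, cU, kind
    if not np.isfinite(log_alpha):
        if log_alpha == -np.inf:  # alpha = 0: always reject
            kind[:] = _ALL
        return cL, cU, kind

    a = 0.5 * (1.0 / s0sq - 1.0 / s1sq)
    b = m / s1sq
    c = log_prior + 0.5 * np.log(s0sq / s1sq) - m * m / (2.0 * s1sq) - log_alpha

    lin = np.abs(a) < 1e-14
    # --- linear case (equal component variances): b d + c >= 0
    if lin.any():
        bl, cl_ = b[lin], c[lin]
        kL = np.where(cl_ >= 0.0, _ALL, _NONE).astype(np.int8)  # b == 0
        cLl = np.full(bl.shape, -np.inf)
        cUl = np.full(bl.shape, np.inf)
        pos_b = bl > 1e-300
        neg_b = bl < -1e-300
        kL[pos_b] = _OUTSIDE
        cUl[pos_b] = -cl_[pos_b] / bl[pos_b]
        kL[neg_b] = _OUTSIDE
        cLl[neg_b] = -cl_[neg_b] / bl[neg_b]
        kind[lin], cL[lin], cU[lin] = kL, cLl, cUl
    # --- quadratic case
    quad = ~lin
    if quad.any():
        aq, bq, cq = a[quad], b[quad], c[quad]
        disc = bq * bq - 4.0 * aq * cq
        kq = np.empty(aq.shape, dtype=np.int8)
        cLq = np.full(aq.shape, -np.inf)
        cUq = np.full(aq.shape, np.inf)
        has_roots = disc > 0.0
        sq = np.sqrt(np.maximum(disc, 0.0))
        r1 = (-bq - sq) / (2.0 * aq)
        r2 = (-bq + sq) / (2.0 * aq)
        lo, hi = np.minimum(r1, r2), np.maximum(r1, r2)
        pos_a = aq > 0.0
        # a > 0: upward parabola; {>=0} is whole line (no real roots) or
        # the complement of (lo, hi)
        m1 = pos_a & ~has_roots
        kq[m1] = _ALL
        m2 = pos_a & has_roots
        kq[m2] = _OUTSIDE
        cLq[m2], cUq[m2] = lo[m2], hi[m2]
        # a < 0: downward parabola; {>=0} is empty or the interval [lo, hi]
        m3 = ~pos_a & ~has_roots
        kq[m3] = _NONE
        m4 = ~pos_a & has_roots
        kq[m4] = _INSIDE
        cLq[m4], cUq[m4] = lo[m4], hi[m4]
        kind[quad], cL[quad], cU[quad] = kq, cLq, cUq
    return cL, cU, kind


def solve_cutoffs(
    theta: MixtureTheta, psi_v: float, alpha: float, direction: Direction = "pos"
) -> RejectionRegion:
    """Solve ``R(d; theta) = alpha`` for one test's rejection region in ``d``."""
    if alpha < 0.0:
        raise ValueError("alpha must be nonnegative")
    with np.errstate(divide="ignore"):
        log_alpha = np.log(alpha) if alpha > 0.0 else -np.inf
    cL, cU, kind = _region_arrays(theta, np.atleast_1d(float(psi_v)), float(log_alpha), direction)
    k = int(kind[0])
    return RejectionRegion(
        cL=float(cL[0]) if k in (_OUTSIDE, _INSIDE) else -np.inf,
        cU=float(cU[0]) if k in (_OUTSIDE, _INSIDE) else np.inf,
        empty=k == _NONE,
        inside=k == _INSIDE,
        full=k == _ALL,
    )


def _null_region_mass(
    theta: MixtureTheta, psi: np.ndarray, log_alpha: float, direction: Direction
) -> np.ndarray:
    """Per-test probability, under the null component N(0, sigma2+psi), of the
    rejection region."""
    cL, cU, kind = _region_arrays(theta, psi, log_alpha, direction)
    s0 = np.sqrt(theta.sigma2 + np.asarray(psi, dtype=float))
    mass = np.zeros(s0.shape)
    out = kind == _OUTSIDE
    if out.any():
        mass[out] = norm.cdf(cL[out] / s0[out]) + norm.sf(cU[out] / s0[out])
    ins = kind == _INSIDE
    if ins.any():
        mass[ins] = norm.cdf(cU[ins] / s0[ins]) - norm.cdf(cL[ins] / s0[ins])
    mass[kind == _ALL] = 1.0
    return mass


def expected_false_discoveries(
    ts: TestSummary, theta: MixtureTheta, alpha: float, direction: Direction = "pos"
) -> float:
    """Phi-based E_hat(V): null mass of every test's rejection region, times p0."""
    with np.errstate(divide="ignore"):
        log_alpha = np.log(alpha) if alpha > 0.0 else -np.inf
    return float(theta.p0 * _null_region_mass(theta, ts.psi, log_alpha, direction).sum())


def _log_ratio(ts: TestSummary, theta: MixtureTheta, direction: Direction) -> np.ndarray:
    log_rp, log_rn = log_likelihood_ratios(ts, theta)
    return log_rp if direction == "pos" else log_rn


def _discovery_count(log_r: np.ndarray, log_alpha: float) -> int:
    return int(np.count_nonzero(log_r >= log_alpha))


def estimate_fdr(
    ts: TestSummary,
    theta: MixtureTheta,
    alpha: float,
    direction: Direction = "pos",
    guard: bool = True,
) -> float:
    """Model-based FDR estimate at cost ``alpha``.

    Guarded (default): ``E_hat(V) / max(D, E_hat(V))``, always in [0, 1] even
    when the realized discovery count undershoots its expectation (relevant at
    very large N).  ``guard=False`` gives the raw ``E_hat(V)/D``.
    """
    with np.errstate(divide="ignore"):
        log_alpha = np.log(alpha) if alpha > 0.0 else -np.inf
    ev = expected_false_discoveries(ts, theta, alpha, direction)
    d_count = _discovery_count(_log_ratio(ts, theta, direction), log_alpha)
    if d_count == 0:
        return 0.0 if ev == 0.0 else (1.0 if guard else np.inf)
    return ev / max(d_count, ev) if guard else ev / d_count


def _find_log_alpha(
    ts: TestSummary,
    theta: MixtureTheta,
    kappa: float,
    direction: Direction,
    guard: bool = True,
) -> float:
    if not 0.0 < kappa < 1.0:
        raise ValueError("kappa must be in (0, 1)")
    log_r = _log_ratio(ts, theta, direction)
    finite = log_r[np.isfinite(log_r)]
    if finite.size == 0:
        return np.inf
    cand = np.unique(finite)[::-1]  # descending: growing rejection sets
    asc = np.sort(finite)  # full sample (with ties) for discovery counts

    def fdr_at(i: int) -> float:
        la = float(cand[i])
        ev = float(theta.p0 * _null_region_mass(theta, ts.psi, la, direction).sum())
        d_count = finite.size - int(np.searchsorted(asc, la, side="left"))
        if d_count == 0:
            return 0.0 if ev == 0.0 else 1.0
        return ev / max(d_count, ev) if guard else ev / d_count

    n = cand.size
    if n <= _EXACT_SCAN_MAX:
        ok = [i for i in range(n) if fdr_at(i) <= kappa]
        return float(cand[max(ok)]) if ok else np.inf

    if fdr_at(0) > kappa:
        return np.inf
    if fdr_at(n - 1) <= kappa:
        return float(cand[n - 1])
    lo, hi = 0, n - 1  # fdr_at(lo) <= kappa < fdr_at(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if fdr_at(mid) <= kappa:
            lo = mid
        else:
            hi = mid
    # local fix-up for small non-monotonicities around the crossing
    while lo + 1 < n and fdr_at(lo + 1) <= kappa:
        lo += 1
    return float(cand[lo])


def find_alpha(
    ts: TestSummary,
    theta: MixtureTheta,
    kappa: float,
    direction: Direction = "pos",
    guard: bool = True,
) -> float:
    """Smallest cost ``alpha`` (largest rejection set) with estimated FDR <= kappa.

    Candidate values are the observed likelihood ratios; ``+inf`` (reject
    nothing) is the fallback when no candidate keeps the estimate within
    ``kappa``.  Below ``_EXACT_SCAN_MAX`` tests every candidate is scanned;
    above, a bisection over the sorted candidates locates the crossing of the
    (empirically monotone) estimated-FDR path, with a local linear fix-up.
    """
    la = _find_log_alpha(ts, theta, kappa, direction, guard)
    return np.inf if np.isinf(la) else float(np.exp(la))


def optimal_rule(
    ts: TestSummary,
    theta: MixtureTheta,
    alpha: float,
    direction: Direction = "pos",
) -> DecisionSet:
    """Reject iff R(d_v; theta) >= alpha in the given direction (ties reject)."""
    if alpha <= 0.0:
        raise ValueError("alpha must be positive")
    log_alpha = float(np.log(alpha))
    log_r = _log_ratio(ts, theta, direction)
    reject = log_r >= log_alpha
    delta = np.where(reject, 1 if direction == "pos" else -1, 0).astype(int)
    fdr_hat = estimate_fdr(ts, theta, alpha, direction)
    if direction == "pos":
        return DecisionSet(delta=delta, kappa=np.nan, alpha_plus=alpha, fdr_hat_plus=fdr_hat)
    return DecisionSet(delta=delta, kappa=np.nan, alpha_minus=alpha, fdr_hat_minus=fdr_hat)


def one_sided_test(
    ts: TestSummary,
    theta: MixtureTheta,
    kappa: float,
    direction: Direction = "pos",
) -> DecisionSet:
    """Calibrate alpha to FDR level kappa, then apply the optimal rule."""
    log_alpha = _find_log_alpha(ts, theta, kappa, direction)
    if np.isinf(log_alpha):
        delta = np.zeros(ts.n_tests, dtype=int)
        if direction == "pos":
            return DecisionSet(delta=delta, kappa=kappa, alpha_plus=np.inf, fdr_hat_plus=0.0)
        return DecisionSet(delta=delta, kappa=kappa, alpha_minus=np.inf, fdr_hat_minus=0.0)
    log_r = _log_ratio(ts, theta, direction)
    reject = log_r >= log_alpha  # exact candidate: the boundary test rejects
    delta = np.where(reject, 1 if direction == "pos" else -1, 0).astype(int)
    ev = float(theta.p0 * _null_region_mass(theta, ts.psi, log_alpha, direction).sum())
    d_count = int(np.count_nonzero(reject))
    fdr_hat = 0.0 if d_count == 0 and ev == 0.0 else ev / max(d_count, ev)
    alpha = float(np.exp(log_alpha))
    if direction == "pos":
        return DecisionSet(delta=delta, kappa=kappa, alpha_plus=alpha, fdr_hat_plus=fdr_hat)
    return DecisionSet(delta=delta, kappa=kappa, alpha_minus=alpha, fdr_hat_minus=fdr_hat)


def two_sided_test(
    ts: TestSummary,
    theta: MixtureTheta,
    kappa_plus: float,
    kappa_minus: float | None = None,
) -> DecisionSet:
    """Three-action test: assign each rejected test a sign.

    Each direction's cost is calibrated independently (possibly different
    levels); a test passing both thresholds takes the direction with the
    larger likelihood ratio (ties go positive).
    """
    kappa_minus = kappa_plus if kappa_minus is None else kappa_minus
    log_rp, log_rn = log_likelihood_ratios(ts, theta)
    la_p = _find_log_alpha(ts, theta, kappa_plus, "pos")
    la_m = _find_log_alpha(ts, theta, kappa_minus, "neg")
    pos = (log_rp >= la_p) & (log_rp >= log_rn)
    neg = (log_rn >= la_m) & (log_rn > log_rp) & ~pos
    delta = np.zeros(ts.n_tests, dtype=int)
    delta[pos] = 1
    delta[neg] = -1

    def _fdr(la: float, direction: Direction) -> float:
        if np.isinf(la):
            return 0.0
        ev = float(theta.p0 * _null_region_mass(theta, ts.psi, la, direction).sum())
        log_r = log_rp if direction == "pos" else log_rn
        d_count = int(np.count_nonzero(log_r >= la))
        return 0.0 if d_count == 0 and ev == 0.0 else ev / max(d_count, ev)

    return DecisionSet(
        delta=delta,
        kappa=(kappa_plus, kappa_minus),
        alpha_plus=float(np.exp(la_p)) if np.isfinite(la_p) else np.inf,
        alpha_minus=float(np.exp(la_m)) if np.isfinite(la_m) else np.inf,
        fdr_hat_plus=_fdr(la_p, "pos"),
        fdr_hat_minus=_fdr(la_m, "neg"),
    )


def outcome_counts(
    delta: np.ndarray,
    o_true: LatentState | np.ndarray,
    sign_errors_as_false: bool = True,
) -> OutcomeCounts:
    """Tabulate realized outcomes of a decision vector against the truth.

    A discovery is false when the test is truly null; with
    ``sign_errors_as_false`` (default) a discovery with the wrong sign also
    counts as false in the direction it was assigned — the three-action loss
    charges misassignment, not just null rejection.
    """
    delta = np.asarray(delta, dtype=int)
    o = o_true.o if isinstance(o_true, LatentState) else np.asarray(o_true, dtype=int)
    if delta.shape != o.shape:
        raise ValueError("delta and o_true must have equal length")
    N = delta.size
    N0 = int(np.count_nonzero(o == 0))
    disc = delta != 0
    D = int(np.count_nonzero(disc))
    correct = disc & (delta == o)
    S = int(np.count_nonzero(correct))
    if sign_errors_as_false:
        V = D - S
    else:
        V = int(np.count_nonzero(disc & (o == 0)))
        S = D - V  # any signed discovery of a true alternative counts as true
    return OutcomeCounts(N=N, N0=N0, V=V, S=S, D=D)
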