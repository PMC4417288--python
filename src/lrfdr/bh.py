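"""Benjamini-Hochberg baseline: per-test t statistics and the step-up procedure.

This is the comparator the likelihood-ratio method is measured against: each
test is summarized by a Welch t statistic ``t_v = d_v / sqrt(psi_hat_v)``
(unequal group variances, Satterthwaite degrees of freedom), converted to a
p-value, and thresholded by the classic BH step-up rule at level kappa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import GroupedResponses, ModelError, summarize_groups

Sidedness = Literal["one_neg", "one_pos", "two"]

_ALTERNATIVE = {"one_neg": "less", "one_pos": "greater", "two": "two-sided"}


@dataclass(frozen=True)
class PValueSet:
    t: np.ndarray
    p: np.ndarray
    df: np.ndarray

    def __post_init__(self) -> None:
        if not (self.t.shape == self.p.shape == self.df.shape):
            raise ModelError("t, p, df must have equal shapes")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ModelError("p-values outside [0, 1]")


def t_statistics(
    g: GroupedResponses,
    sided: Sidedness = "two",
    pooled: bool = False,
    normal_approx: bool = False,
) -> PValueSet:
    """Per-test two-sample t tests (case minus control).

    Welch by default, matching the model's heteroscedastic
    ``psi_v = phi_v1/n1 + phi_v2/n2``; ``pooled=True`` gives the equal-variance
    t.  ``normal_approx=True`` swaps the t reference distribution for N(0, 1),
    the asymptotic null of ``d_v / sqrt(psi_hat_v)``.
    """
    if sided not in _ALTERNATIVE:
        raise ValueError(f"sided must be one of {sorted(_ALTERNATIVE)}, got {sided!r}")
    summarize_groups(g)  # validates, and errors on zero-variance tests
    res = stats.ttest_ind(
        g.y2, g.y1, axis=1, equal_var=pooled, alternative=_ALTERNATIVE[sided]
    )
    t = np.asarray(res.statistic, dtype=float)
    df = np.broadcast_to(np.asarray(res.df, dtype=float), t.shape).copy()
    if normal_approx:
        if sided == "two":
            p = 2.0 * stats.norm.sf(np.abs(t))
        elif sided == "one_pos":
            p = stats.norm.sf(t)
        else:
            p = stats.norm.cdf(t)
    else:
        p = np.asarray(res.pvalue, dtype=float)
    return PValueSet(t=t, p=p, df=df)


def bh_procedure(p: np.ndarray, kappa: float) -> np.ndarray:
    """BH step-up at level kappa: boolean rejection vector.

    Sort the p-values, find the largest i with p_(i) <= i*kappa/N, reject the
    i smallest.  Delegates to statsmodels' ``fdr_bh``.
    """
    p = np.asarray(p, dtype=float)
    if not 0.0 < kappa < 1.0:
        raise ValueError("kappa must be in (0, 1)")
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a nonempty 1-d vector")
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=kappa, method="fdr_bh")
    return reject
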