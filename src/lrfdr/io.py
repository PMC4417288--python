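"""Delimited-text readers and writers for the package's tables.

Everything is plain text: comma-delimited by default, tab accepted.  Floats
round-trip losslessly (written with repr precision).  Missing-value tokens
are rejected on read — a summary table with holes is an upstream error, not
something to impute silently.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .em import EMFit
from .model import GroupedResponses, MixtureTheta, ModelError, TestSummary
from .testing import DecisionSet


def _read_table(path: str | Path, header: bool) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", header=0 if header else None)
    if df.isna().any().any():
        raise ModelError(f"{path}: missing values are not allowed")
    return df


def read_test_summary(path: str | Path) -> TestSummary:
    """Read a `test_id,d,psi` table (any order of extra columns tolerated)."""
    df = _read_table(path, header=True)
    for col in ("d", "psi"):
        if col not in df.columns:
            raise ModelError(f"{path}: required column {col!r} not found")
    return TestSummary(d=df["d"].to_numpy(float), psi=df["psi"].to_numpy(float))


def write_test_summary(ts: TestSummary, path: str | Path) -> None:
    pd.DataFrame(
        {"test_id": np.arange(ts.n_tests), "d": ts.d, "psi": ts.psi}
    ).to_csv(path, index=False)


def read_grouped(path1: str | Path, path2: str | Path) -> GroupedResponses:
    """Read two headerless matrices (rows = tests, columns = subjects)."""
    y1 = _read_table(path1, header=False).to_numpy(float)
    y2 = _read_table(path2, header=False).to_numpy(float)
    return GroupedResponses(y1=y1, y2=y2)


def write_grouped(g: GroupedResponses, path1: str | Path, path2: str | Path) -> None:
    pd.DataFrame(g.y1).to_csv(path1, index=False, header=False)
    pd.DataFrame(g.y2).to_csv(path2, index=False, header=False)


_THETA_KEYS = ("p0", "p1", "pm1", "mu", "sigma2", "tau2")


def write_theta(theta: MixtureTheta, path: str | Path) -> None:
    """Machine-readable key=value parameter file."""
    lines = [f"{k}={float(getattr(theta, k))!r}" for k in _THETA_KEYS]
    Path(path).write_text("\n".join(lines) + "\n")


def read_theta(path: str | Path) -> MixtureTheta:
    vals: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        if key.strip() not in _THETA_KEYS:
            raise ModelError(f"{path}: unknown parameter {key.strip()!r}")
        vals[key.strip()] = float(val)
    missing = set(_THETA_KEYS) - set(vals)
    if missing:
        raise ModelError(f"{path}: missing parameters {sorted(missing)}")
    return MixtureTheta(**vals)


def format_fit_report(fit: EMFit, direction: str = "pos") -> str:
    """Human-readable parameter table (signed mu shown per the tested direction)."""
    t = fit.theta
    mu_signed = -t.mu if direction == "neg" and t.p1 == 0.0 else t.mu
    rows = [
        ("mu", mu_signed),
        ("sigma2", t.sigma2),
        ("tau2", t.tau2),
        ("P0", t.p0),
        ("P1", t.p1),
        ("P-1", t.pm1),
    ]
    width = max(len(k) for k, _ in rows)
    body = "\n".join(f"{k:<{width}}  {v: .6f}" for k, v in rows)
    tail = (
        f"\nlog-likelihood  {fit.loglik:.6f}"
        f"\nconverged       {fit.converged}"
        f"\niterations      {fit.n_iter}"
    )
    return body + tail + "\n"


def write_decisions(
    ds: DecisionSet,
    ts: TestSummary,
    log_rp: np.ndarray,
    log_rn: np.ndarray,
    path: str | Path,
) -> None:
    """Per-test decision table `test_id,d,psi,R_pos,R_neg,delta`."""
    with np.errstate(over="ignore"):
        pd.DataFrame(
            {
                "test_id": np.arange(ts.n_tests),
                "d": ts.d,
                "psi": ts.psi,
                "R_pos": np.exp(log_rp),
                "R_neg": np.exp(log_rn),
                "delta": ds.delta,
            }
        ).to_csv(path, index=False)


def write_decision_summary(ds: DecisionSet, path: str | Path) -> None:
    kappa = ds.kappa if isinstance(ds.kappa, tuple) else (ds.kappa,)
    kv: dict[str, object] = {
        "discoveries": ds.n_discoveries,
        "kappa": ",".join(repr(float(k)) for k in kappa),
        "alpha_plus": ds.alpha_plus,
        "alpha_minus": ds.alpha_minus,
        "fdr_hat_plus": ds.fdr_hat_plus,
        "fdr_hat_minus": ds.fdr_hat_minus,
    }
    lines = [
        f"{k}={float(v)!r}" if isinstance(v, (float, np.floating)) else f"{k}={v}"
        for k, v in kv.items()
        if v is not None
    ]
    Path(path).write_text("\n".join(lines) + "\n")
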