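"""Residual heterogeneity and publication-bias diagnostics.

Cochran's Q is the weighted residual sum of squares from the
fixed-effects (no random components) weighted least-squares fit on the
same moderator design as the mixed model; under homogeneity it is
chi-square with k − p degrees of freedom.  The multilevel I² expresses
the summed variance components relative to the "typical" sampling
variance ṽ of Higgins & Thompson:

    I² = 100 · Σσ² / (Σσ² + ṽ),   ṽ = (k−1) Σw / ((Σw)² − Σw²),  w = 1/v.

Funnel asymmetry is tested with the Begg–Mazumdar rank correlation:
Kendall's tau between the standardized deviations from the
fixed-effect pooled estimate, (z_i − ẑ)/√(v_i − v̄), and the sampling
variances v_i.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .model import MetaFit, MetaModelSpec, build_design, _drop_degenerate


@dataclass(frozen=True)
class HeterogeneityReport:
    Q: float
    df: int
    p_value: float
    i_squared_pct: float
    i_squared_by_factor: dict[str, float]
    sigma2_components: dict[str, float]
    typical_v: float

    def to_dict(self) -> dict:
        return {
            "Q": self.Q,
            "df": self.df,
            "p_value": self.p_value,
            "I2_total": self.i_squared_pct,
            "I2_by_factor": dict(self.i_squared_by_factor),
            "sigma2": dict(self.sigma2_components),
            "typical_v": self.typical_v,
        }


def q_statistic(df: pd.DataFrame, moderators=("intercept",)) -> tuple[float, int, float]:
    """Residual Q from the fixed-effects weighted LS fit on the design.

    Returns (Q, df, p) with df = k − p and p from chi-square(df).
    """
    z = df["zr"].to_numpy(dtype=float)
    v = df["var_zr"].to_numpy(dtype=float)
    X, names = build_design(df, tuple(moderators))
    X, names, _ = _drop_degenerate(X, names)
    k, p = X.shape
    if k <= p:
        raise ValueError(f"k={k} must exceed p={p}")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design")
    w = 1.0 / v
    XtWX = X.T @ (w[:, None] * X)
    beta = linalg.solve(XtWX, X.T @ (w * z), assume_a="pos")
    resid = z - X @ beta
    Q = float(np.sum(w * resid**2))
    dof = k - p
    return Q, dof, float(stats.chi2.sf(Q, dof))


def typical_sampling_variance(v: np.ndarray) -> float:
    """Higgins–Thompson ṽ = (k−1)Σw / ((Σw)² − Σw²)."""
    v = np.asarray(v, dtype=float)
    k = v.size
    if k < 2:
        raise ValueError("need at least two effect sizes")
    w = 1.0 / v
    return float((k - 1) * w.sum() / (w.sum() ** 2 - (w**2).sum()))


def i_squared(fit: MetaFit, df: pd.DataFrame) -> tuple[float, dict[str, float], float]:
    """Multilevel I² (percent) plus per-factor shares and ṽ."""
    if not fit.converged:
        raise RuntimeError("cannot compute I2 from a non-converged fit")
    vt = typical_sampling_variance(df["var_zr"].to_numpy(dtype=float))
    total_s2 = sum(fit.sigma2.values())
    denom = total_s2 + vt
    total = 100.0 * total_s2 / denom
    by_factor = {f: 100.0 * s2 / denom for f, s2 in fit.sigma2.items()}
    return total, by_factor, vt


def heterogeneity_report(
    fit: MetaFit, df: pd.DataFrame, moderators=None
) -> HeterogeneityReport:
    mods = tuple(moderators) if moderators is not None else fit.spec.moderators
    Q, dof, p = q_statistic(df, mods)
    total, by_factor, vt = i_squared(fit, df)
    return HeterogeneityReport(
        Q=Q,
        df=dof,
        p_value=p,
        i_squared_pct=total,
        i_squared_by_factor=by_factor,
        sigma2_components=dict(fit.sigma2),
        typical_v=vt,
    )


def _standardized_effects(z: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Begg–Mazumdar construction against the fixed-effect pooled mean."""
    w = 1.0 / v
    z_pool = float(np.sum(w * z) / w.sum())
    v_pool = 1.0 / float(w.sum())
    denom = v - v_pool
    # v_i >= 1/sum(w) with equality only for k=1; guard exact ties anyway
    denom = np.maximum(denom, np.finfo(float).tiny)
    return (z - z_pool) / np.sqrt(denom), v


def _exact_tau_p(x: np.ndarray, y: np.ndarray, tau_obs: float) -> float:
    """Two-sided exact permutation p for Kendall tau, k <= 8."""
    k = len(x)
    count = 0
    total = 0
    for perm in itertools.permutations(range(k)):
        t = stats.kendalltau(x[list(perm)], y).statistic
        total += 1
        if abs(t) >= abs(tau_obs) - 1e-12:
            count += 1
    return count / total


def begg_rank_test(
    df: pd.DataFrame, exact: bool = False, residuals_of: MetaFit | None = None
) -> tuple[float, float]:
    """Rank-correlation funnel-asymmetry test.

    Standardizes each effect against the fixed-effect pooled estimate
    (the no-moderator construction; pass ``residuals_of`` to use a
    fitted model's fixed-effect residuals instead) and returns tau-b
    between standardized effects and sampling variances with the
    tie-corrected normal two-sided p.  ``exact=True`` enumerates the
    permutation distribution (k ≤ 8 only).
    """
    z = df["zr"].to_numpy(dtype=float)
    v = df["var_zr"].to_numpy(dtype=float)
    if len(z) < 3:
        raise ValueError("need at least three effect sizes")
    if residuals_of is not None:
        X, names = build_design(df, residuals_of.spec.moderators)
        X, names, _ = _drop_degenerate(X, names)
        w = 1.0 / v
        XtWX = X.T @ (w[:, None] * X)
        beta = linalg.solve(XtWX, X.T @ (w * z), assume_a="pos")
        resid = z - X @ beta
        star = resid / np.sqrt(np.maximum(v - 1.0 / w.sum(), np.finfo(float).tiny))
    else:
        star, v = _standardized_effects(z, v)
    res = stats.kendalltau(star, v)
    tau = float(res.statistic)
    if exact:
        if len(z) > 8:
            raise ValueError("exact permutation p limited to k <= 8")
        return tau, float(_exact_tau_p(star, v, tau))
    return tau, float(res.pvalue)


def funnel_data(df: pd.DataFrame, fit: MetaFit) -> pd.DataFrame:
    """Per-record (zr, se_zr) points plus the model intercept as center."""
    if not fit.converged:
        raise RuntimeError("funnel center requires a converged fit")
    out = pd.DataFrame(
        {
            "record_id": df["record_id"],
            "zr": df["zr"].to_numpy(dtype=float),
            "se_zr": np.sqrt(df["var_zr"].to_numpy(dtype=float)),
        }
    )
    out.attrs["center"] = fit.coef("intercept")[0]
    return out
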