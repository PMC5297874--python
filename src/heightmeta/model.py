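"""Crossed-random-effects meta-analytic model, fitted by REML.

The marginal model for the Fisher-z effects is

    z = X beta + Z_a u + Z_c w + e,
    u ~ N(0, sigma2_author I),  w ~ N(0, sigma2_country I),
    e_i ~ independent N(0, v_i),  v_i = 1/(N_i - 3) known,

with author group and country entering as *crossed* random intercepts
(an author group can span countries and vice versa).  The restricted
log-likelihood is maximized over the two variance components; at any
candidate (sigma2_a, sigma2_c) the fixed effects are the GLS solution
and drop out of the restricted objective:

    l_R = -1/2 [ (k - p) log 2*pi + log|V| + log|X' V^-1 X| + r' V^-1 r ],

with V = diag(v) + sigma2_a Z_a Z_a' + sigma2_c Z_c Z_c' and r the GLS
residual.  Optimization runs on the log-variance scale (Nelder-Mead,
deterministic method-of-moments start) and the 0 boundary of each
component is handled explicitly by profiling the other component with
one (or both) pinned at zero; the best of the interior and boundary
candidates is returned.  ML is available for likelihood-ratio work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

MODERATOR_CHOICES = ("intercept", "western", "year_centered", "western:year_centered")
RANDOM_FACTOR_COLUMNS = {"author_group": "author_group_id", "country": "country_name"}


@dataclass(frozen=True)
class MetaModelSpec:
    """Fixed-effect design and random-factor structure of one fit."""

    moderators: tuple[str, ...] = ("intercept",)
    random_factors: tuple[str, ...] = ("author_group", "country")
    method: str = "REML"  # or "ML"
    tol: float = 1e-10
    max_iter: int = 2000
    var_lower: float = 0.0

    def __post_init__(self):
        if "intercept" not in self.moderators:
            object.__setattr__(self, "moderators", ("intercept",) + tuple(self.moderators))
        for m in self.moderators:
            if m not in MODERATOR_CHOICES:
                raise ValueError(f"unknown moderator {m!r}")
        for f in self.random_factors:
            if f not in RANDOM_FACTOR_COLUMNS:
                raise ValueError(f"unknown random factor {f!r}")
        if self.method not in ("REML", "ML"):
            raise ValueError("method must be REML or ML")


@dataclass
class MetaFit:
    """Result of one model fit on the Fisher-z scale."""

    coef_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    sigma2: dict[str, float]
    loglik: float
    method: str
    k: int
    p: int
    converged: bool
    mean_year_used: float
    spec: MetaModelSpec
    profile_ok: bool | None = None
    profiles: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    dropped_moderators: list[str] = field(default_factory=list)

    @property
    def sigma2_author(self) -> float:
        return self.sigma2.get("author_group", 0.0)

    @property
    def sigma2_country(self) -> float:
        return self.sigma2.get("country", 0.0)

    def coef(self, name: str) -> tuple[float, float]:
        if name not in self.coef_names:
            raise KeyError(f"no coefficient {name!r} in fit (have {self.coef_names})")
        i = self.coef_names.index(name)
        return float(self.beta[i]), float(self.se[i])

    def to_dict(self) -> dict:
        return {
            "coefficients": {
                name: {"estimate": float(b), "se": float(s)}
                for name, b, s in zip(self.coef_names, self.beta, self.se)
            },
            "sigma2": {k: float(v) for k, v in self.sigma2.items()},
            "loglik": float(self.loglik),
            "method": self.method,
            "k": self.k,
            "p": self.p,
            "converged": self.converged,
            "profile_ok": self.profile_ok,
            "mean_year_used": self.mean_year_used,
            "dropped_moderators": self.dropped_moderators,
        }


def build_design(df: pd.DataFrame, moderators: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design matrix; degenerate columns are dropped."""
    cols, names = [], []
    k = len(df)
    for m in moderators:
        if m == "intercept":
            cols.append(np.ones(k))
            names.append("intercept")
        elif m == "western":
            cols.append(df["western"].to_numpy(dtype=float))
            names.append("western")
        elif m == "year_centered":
            cols.append(df["year_centered"].to_numpy(dtype=float))
            names.append("year_centered")
        elif m == "western:year_centered":
            cols.append(
                df["western"].to_numpy(dtype=float) * df["year_centered"].to_numpy(dtype=float)
            )
            names.append("western:year_centered")
    X = np.column_stack(cols)
    return X, names


def _drop_degenerate(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Drop constant non-intercept columns (e.g. western in an all-western subset)."""
    keep, dropped = [], []
    for j, name in enumerate(names):
        if name != "intercept" and np.ptp(X[:, j]) == 0.0:
            dropped.append(name)
        else:
            keep.append(j)
    return X[:, keep], [names[j] for j in keep], dropped


def _factor_matrix(df: pd.DataFrame, column: str) -> np.ndarray:
    codes, _ = pd.factorize(df[column].to_numpy())
    Z = np.zeros((len(codes), codes.max() + 1))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def _gls(X: np.ndarray, z: np.ndarray, Vinv_X: np.ndarray, Vinv_z: np.ndarray):
    XtVinvX = X.T @ Vinv_X
    XtVinvz = X.T @ Vinv_z
    beta = linalg.solve(XtVinvX, XtVinvz, assume_a="pos")
    return beta, XtVinvX


def restricted_loglik(
    sigma2: Sequence[float],
    X: np.ndarray,
    z: np.ndarray,
    v: np.ndarray,
    Z_list: Sequence[np.ndarray],
    method: str = "REML",
) -> float:
    """Exact (restricted) log-likelihood at given variance components.

    Returns -inf for non-positive-definite V (never happens for
    sigma2 >= 0 and v > 0, but guards optimizer excursions).
    """
    k, p = X.shape
    V = np.diag(v.astype(float)).copy()
    for s2, Z in zip(sigma2, Z_list):
        if s2 < 0:
            return -np.inf
        if s2 > 0:
            V += s2 * (Z @ Z.T)
    try:
        c, low = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError:
        return -np.inf
    logdetV = 2.0 * float(np.sum(np.log(np.diag(c))))
    Vinv_X = linalg.cho_solve((c, low), X)
    Vinv_z = linalg.cho_solve((c, low), z)
    beta, XtVinvX = _gls(X, z, Vinv_X, Vinv_z)
    resid = z - X @ beta
    quad = float(resid @ linalg.cho_solve((c, low), resid))
    if method == "ML":
        return -0.5 * (k * math.log(2 * math.pi) + logdetV + quad)
    sign, logdetXtVX = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        return -np.inf
    # +0.5 log|X'X| makes the restricted likelihood invariant to linear
    # reparameterization of the fixed effects (the metafor convention),
    # so log-likelihoods are directly comparable across toolchains
    _, logdetXtX = np.linalg.slogdet(X.T @ X)
    return -0.5 * (
        (k - p) * math.log(2 * math.pi) + logdetV + logdetXtVX + quad - logdetXtX
    )


def _mom_start(X, z, v, n_components) -> float:
    """Method-of-moments total heterogeneity (DerSimonian–Laird style)."""
    w = 1.0 / v
    W = np.diag(w)
    XtWX = X.T @ W @ X
    beta = linalg.solve(XtWX, X.T @ (w * z), assume_a="pos")
    resid = z - X @ beta
    Q = float(np.sum(w * resid**2))
    k, p = X.shape
    # trace correction for a meta-regression
    P = W - W @ X @ linalg.solve(XtWX, X.T @ W, assume_a="pos")
    denom = float(np.trace(P))
    tau2 = max((Q - (k - p)) / denom, 1e-4) if denom > 0 else 1e-4
    return tau2 / max(n_components, 1)


def fit_model(df: pd.DataFrame, spec: MetaModelSpec) -> MetaFit:
    """Fit the mixed-effects meta-analytic model by REML (or ML).

    ``df`` is the effects table from :func:`heightmeta.effects.compute_effects`
    (columns zr, var_zr, western, year_centered, author_group_id,
    country_name).  Returns ``converged=False`` rather than raising when
    the optimizer stalls.
    """
    z = df["zr"].to_numpy(dtype=float)
    v = df["var_zr"].to_numpy(dtype=float)
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be positive")
    X, names = build_design(df, spec.moderators)
    X, names, dropped = _drop_degenerate(X, names)
    k, p = X.shape
    if k <= p:
        raise ValueError(f"too few effect sizes (k={k}) for p={p} coefficients")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient fixed-effect design")
    Z_list = [_factor_matrix(df, RANDOM_FACTOR_COLUMNS[f]) for f in spec.random_factors]
    q = len(Z_list)

    def nll_log(g):
        return -restricted_loglik(np.exp(g), X, z, v, Z_list, spec.method)

    candidates: list[tuple[np.ndarray, float, bool]] = []
    converged = True
    if q > 0:
        start = math.log(_mom_start(X, z, v, q))
        res = optimize.minimize(
            nll_log,
            np.full(q, start),
            method="Nelder-Mead",
            options={
                "xatol": spec.tol ** 0.5,
                "fatol": spec.tol,
                "maxiter": spec.max_iter,
                "maxfev": spec.max_iter,
            },
        )
        interior = np.exp(res.x)
        # treat tiny interior optima as boundary solutions
        interior[interior < 1e-10] = 0.0
        candidates.append((interior, restricted_loglik(interior, X, z, v, Z_list, spec.method), res.success))
        # boundary candidates: each subset of components pinned to the lower bound
        for mask in range(1, 2**q):
            pinned = [(mask >> i) & 1 for i in range(q)]
            free = [i for i in range(q) if not pinned[i]]
            if not free:
                s2 = np.full(q, spec.var_lower)
                candidates.append((s2, restricted_loglik(s2, X, z, v, Z_list, spec.method), True))
                continue

            def nll_free(g, free=free, pinned=pinned):
                s2 = np.full(q, spec.var_lower)
                s2[free] = np.exp(np.atleast_1d(g))
                return -restricted_loglik(s2, X, z, v, Z_list, spec.method)

            if len(free) == 1:
                r1 = optimize.minimize_scalar(
                    nll_free, bounds=(math.log(1e-12), math.log(10.0)), method="bounded",
                    options={"xatol": 1e-10},
                )
                s2 = np.full(q, spec.var_lower)
                s2[free] = math.exp(r1.x)
                s2[s2 < 1e-10] = 0.0
            else:
                r1 = optimize.minimize(
                    nll_free, np.full(len(free), start), method="Nelder-Mead",
                    options={"xatol": spec.tol ** 0.5, "fatol": spec.tol, "maxiter": spec.max_iter},
                )
                s2 = np.full(q, spec.var_lower)
                s2[free] = np.exp(r1.x)
                s2[s2 < 1e-10] = 0.0
            candidates.append((s2, restricted_loglik(s2, X, z, v, Z_list, spec.method), True))
        sigma2, loglik, ok = max(candidates, key=lambda c: c[1])
        converged = bool(ok and np.isfinite(loglik))
    else:
        sigma2 = np.array([])
        loglik = restricted_loglik(sigma2, X, z, v, Z_list, spec.method)
        converged = bool(np.isfinite(loglik))

    # final GLS at the optimum
    V = np.diag(v.astype(float)).copy()
    for s2, Z in zip(sigma2, Z_list):
        V += s2 * (Z @ Z.T)
    c, low = linalg.cho_factor(V, lower=True)
    Vinv_X = linalg.cho_solve((c, low), X)
    Vinv_z = linalg.cho_solve((c, low), z)
    beta, XtVinvX = _gls(X, z, Vinv_X, Vinv_z)
    vcov = linalg.inv(XtVinvX)
    se = np.sqrt(np.diag(vcov))

    mean_year = float(df["year_published"].mean()) if "year_published" in df else float("nan")
    return MetaFit(
        coef_names=names,
        beta=np.asarray(beta, dtype=float),
        se=se,
        vcov=vcov,
        sigma2={f: float(s2) for f, s2 in zip(spec.random_factors, sigma2)},
        loglik=float(loglik),
        method=spec.method,
        k=k,
        p=p,
        converged=converged,
        mean_year_used=mean_year,
        spec=spec,
        dropped_moderators=dropped,
    )


# alias matching the estimation method most callers want
fit_reml = fit_model


def pooled_estimate(
    fit: MetaFit, at: Mapping[str, float] | None = None, level: float = 0.95
) -> dict:
    """Model prediction back-transformed to the correlation scale.

    The Wald CI is formed on the z scale (estimate ± z_{α/2}·SE) and
    each endpoint mapped through tanh, so the r-scale CI is the
    monotone image of the z-scale one and always lies in (−1, 1).
    ``at`` gives moderator values (default: all zero, i.e. the
    intercept: a non-western study at the mean publication year).
    """
    if not fit.converged:
        raise RuntimeError("cannot summarize a non-converged fit")
    at = dict(at or {})
    cvec = np.zeros(fit.p)
    for i, name in enumerate(fit.coef_names):
        cvec[i] = 1.0 if name == "intercept" else float(at.get(name, 0.0))
    est = float(cvec @ fit.beta)
    se = float(math.sqrt(cvec @ fit.vcov @ cvec))
    zcrit = float(stats.norm.ppf(0.5 + level / 2))
    lo, hi = est - zcrit * se, est + zcrit * se
    return {
        "z": est,
        "se_z": se,
        "r": math.tanh(est),
        "ci_low": math.tanh(lo),
        "ci_high": math.tanh(hi),
        "level": level,
    }


def wald_test(fit: MetaFit, coefficient: str) -> tuple[float, float]:
    """Wald z statistic and two-sided normal p for one coefficient."""
    est, se = fit.coef(coefficient)
    stat = est / se
    p = 2.0 * float(stats.norm.sf(abs(stat)))
    return stat, p


def profile_likelihood_check(
    fit: MetaFit,
    df: pd.DataFrame,
    spec: MetaModelSpec | None = None,
    grid: Sequence[float] = (0.25, 0.5, 0.75, 1.25, 1.5, 2.0, 4.0),
    tol: float = 1e-6,
) -> MetaFit:
    """Likelihood-surface profile diagnostic against false convergence.

    For each variance component the restricted log-likelihood is
    profiled on a multiplicative grid around the estimate, re-optimizing
    the other component at every grid point.  ``profile_ok`` is set true
    iff no profiled point beats the reported optimum by more than
    ``tol``.  A component estimated at the 0 boundary is probed on an
    absolute grid away from zero; a decreasing profile there counts as a
    boundary maximum.  Returns the fit with ``profile_ok`` and the
    profile curves filled in.
    """
    spec = spec or fit.spec
    z = df["zr"].to_numpy(dtype=float)
    v = df["var_zr"].to_numpy(dtype=float)
    X, names = build_design(df, spec.moderators)
    X, names, _ = _drop_degenerate(X, names)
    Z_list = [_factor_matrix(df, RANDOM_FACTOR_COLUMNS[f]) for f in spec.random_factors]
    q = len(Z_list)
    factors = list(spec.random_factors)
    est = np.array([fit.sigma2.get(f, 0.0) for f in factors])
    ok = True
    curves: dict[str, list[tuple[float, float]]] = {}
    for i, factor in enumerate(factors):
        others = [j for j in range(q) if j != i]
        if est[i] > 0:
            points = [m * est[i] for m in grid]
        else:
            scale = float(np.median(v))
            points = [scale * m for m in (0.01, 0.05, 0.1, 0.5, 1.0)]
        curve = []
        for val in points:
            def nll(g, val=val, i=i, others=others):
                s2 = np.empty(q)
                s2[i] = val
                s2[others] = np.exp(np.atleast_1d(g))
                return -restricted_loglik(s2, X, z, v, Z_list, fit.method)

            if others:
                start = math.log(max(est[others[0]], 1e-6))
                r1 = optimize.minimize_scalar(
                    nll, bounds=(math.log(1e-12), math.log(10.0)), method="bounded",
                    options={"xatol": 1e-10},
                )
                ll = -float(r1.fun)
                # 0 boundary for the re-optimized component
                s2b = np.empty(q)
                s2b[i] = val
                s2b[others] = 0.0
                ll = max(ll, restricted_loglik(s2b, X, z, v, Z_list, fit.method))
            else:
                s2 = np.array([val])
                ll = restricted_loglik(s2, X, z, v, Z_list, fit.method)
            curve.append((float(val), float(ll)))
            if ll > fit.loglik + tol:
                ok = False
        curves[factor] = curve
    fit.profile_ok = ok
    fit.profiles = curves
    return fit
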