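"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the restricted
likelihood is evaluated through the error-contrast definition (density
of A'z for an orthonormal null-space basis A of X'), and the optimum is
located by brute-force grid refinement; Kendall's tau is recomputed by
exhaustive pair counting.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import linalg, stats


def contrast_reml_loglik(sigma2_a, sigma2_c, X, z, v, Za, Zc):
    """REML log-likelihood via error contrasts: log N(A'z; 0, A'VA).

    For orthonormal A spanning null(X') this equals the standard REML
    expression with the +0.5 log|X'X| convention.
    """
    V = np.diag(np.asarray(v, float)) + sigma2_a * (Za @ Za.T) + sigma2_c * (Zc @ Zc.T)
    A = linalg.null_space(X.T)
    return float(stats.multivariate_normal.logpdf(A.T @ z, mean=None, cov=A.T @ V @ A))


def grid_profile_reml(X, z, v, Za, Zc, upper=1.0, n_grid=25, n_refine=4):
    """Brute-force grid/profile search for the REML optimum.

    Successively refines a 2-D grid over (sigma2_a, sigma2_c) including
    the 0 boundary.  Returns (sigma2_a, sigma2_c, loglik, beta).
    """
    lo_a = lo_c = 0.0
    hi_a = hi_c = upper
    best = (0.0, 0.0, -np.inf)
    for _ in range(n_refine):
        grid_a = np.linspace(lo_a, hi_a, n_grid)
        grid_c = np.linspace(lo_c, hi_c, n_grid)
        for sa in grid_a:
            for sc in grid_c:
                ll = contrast_reml_loglik(sa, sc, X, z, v, Za, Zc)
                if ll > best[2]:
                    best = (sa, sc, ll)
        step_a = grid_a[1] - grid_a[0]
        step_c = grid_c[1] - grid_c[0]
        lo_a, hi_a = max(best[0] - step_a, 0.0), best[0] + step_a
        lo_c, hi_c = max(best[1] - step_c, 0.0), best[1] + step_c
    sa, sc, ll = best
    V = np.diag(np.asarray(v, float)) + sa * (Za @ Za.T) + sc * (Zc @ Zc.T)
    Vinv = linalg.inv(V)
    beta = linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ z)
    return sa, sc, ll, beta


def kendall_tau_by_pairs(x, y):
    """Tau-b by exhaustive concordant/discordant pair counting."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    conc = disc = ties_x = ties_y = n0 = 0
    for i, j in itertools.combinations(range(len(x)), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        n0 += 1
        if dx == 0:
            ties_x += 1
        if dy == 0:
            ties_y += 1
        if dx * dy > 0:
            conc += 1
        elif dx * dy < 0:
            disc += 1
    denom = np.sqrt((n0 - ties_x) * (n0 - ties_y))
    return (conc - disc) / denom
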