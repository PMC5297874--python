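"""Fisher-z effect sizes and sample-size recovery/imputation rules.

The meta-analysis operates on the variance-stabilized scale: each
Pearson correlation r becomes zr = 0.5·ln((1+r)/(1−r)) = artanh(r) with
sampling variance 1/(N−3).  Where a publication omits N, it is
recovered from whatever was printed instead:

* from a reported SE of r via SE_r ≈ (1−r²)/√(N−2);
* from a significance category (p < .05/.01/.001) via the t-statistic
  identity r = t/√(t² + df) with t ∈ {1.96, 2.58, 3.59} and df = N − 1,
  yielding a *lower-limit* N (hence rounded down);
* as the median N across companion studies when nothing else exists.

All recovered sample sizes are integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import Dataset, PCategory

#: t quantiles substituted for significance categories.
T_FOR_CATEGORY = {
    PCategory.P_LT_05: 1.96,
    PCategory.P_LT_01: 2.58,
    PCategory.P_LT_001: 3.59,
}


@dataclass(frozen=True)
class EffectSize:
    record_id: str
    zr: float
    var_zr: float
    n_used: int


def fisher_z(r):
    """Variance-stabilizing transform zr = artanh(r); odd in r."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1 for the Fisher transform")
    return np.arctanh(r) if r.ndim else float(np.arctanh(r))


def inv_fisher_z(zr):
    """Back-transform to the correlation scale: r = tanh(zr)."""
    zr = np.asarray(zr, dtype=float)
    if not np.all(np.isfinite(zr)):
        raise ValueError("zr must be finite")
    return np.tanh(zr) if zr.ndim else float(np.tanh(zr))


def se_zr(n) -> float:
    """Standard error of zr: 1/√(N−3); strictly decreasing in N."""
    n = int(n)
    if n <= 3:
        raise ValueError(f"N={n}: need at least 4 couples for a finite variance")
    return 1.0 / math.sqrt(n - 3)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def n_from_se(r: float, se_r: float, rounding: str = "half_away") -> int:
    """Recover N from a reported SE of r via SE_r = (1−r²)/√(N−2).

    ``rounding`` is ``"half_away"`` (default) or ``"floor"``.
    """
    if not (abs(r) < 1):
        raise ValueError("|r| must be < 1")
    if se_r <= 0:
        raise ValueError("se_r must be positive")
    raw = ((1.0 - r * r) / se_r) ** 2 + 2.0
    n = math.floor(raw) if rounding == "floor" else _round_half_away(raw)
    if n < 4:
        raise ValueError(f"recovered N={n} < 4 (SE too large to be informative)")
    return n


def n_from_p_category(r: float, category: PCategory | str, rounding: str = "floor") -> int:
    """Lower-limit N from a significance category.

    Inverts r = t/√(t² + df) with df = N − 1, so N = t²(1−r²)/r² + 1.
    Rounded down by default: the category only bounds significance, so
    flooring preserves the lower-limit reading.
    """
    if r == 0:
        raise ValueError("r = 0: significance category carries no sample-size information")
    if not (abs(r) < 1):
        raise ValueError("|r| must be < 1")
    t = T_FOR_CATEGORY[PCategory(category)]
    df = t * t * (1.0 - r * r) / (r * r)
    raw = df + 1.0
    n = math.floor(raw) if rounding == "floor" else _round_half_away(raw)
    if n < 4:
        raise ValueError(f"recovered N={n} < 4")
    return n


def impute_median_n(reference_ns: Iterable[int], rounding: str = "half_away") -> int:
    """Median of companion-study sample sizes, as an integer.

    Even counts take the mean of the two central values, rounded
    half-away-from-zero by default.
    """
    ns = sorted(int(n) for n in reference_ns)
    if not ns:
        raise ValueError("need at least one reference N")
    med = float(np.median(ns))
    return math.floor(med) if rounding == "floor" else _round_half_away(med)


def weighted_mean_r(
    rs: Sequence[float], ns: Sequence[int], scale: str = "z"
) -> tuple[float, int]:
    """Sample-size-weighted average of correlations from one source.

    Default combines on the Fisher-z scale (variance stabilized) with
    weights N_i, then back-transforms; ``scale="r"`` averages raw
    correlations instead, for sensitivity analysis.  Returns the pooled
    correlation and the combined N = ΣN_i.
    """
    rs = np.asarray(rs, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if rs.size == 0:
        raise ValueError("empty input")
    if rs.shape != ns.shape:
        raise ValueError("rs and ns must have equal length")
    if np.any(ns < 4):
        raise ValueError("all N must be >= 4")
    if scale == "z":
        pooled = float(np.tanh(np.average(np.arctanh(rs), weights=ns)))
    elif scale == "r":
        pooled = float(np.average(rs, weights=ns))
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return pooled, int(ns.sum())


def compute_effects(ds: Dataset) -> pd.DataFrame:
    """Table-in/table-out transform: study table + zr, var_zr, n_used.

    ``n_used`` is the record's final (possibly imputed) N; weighting is
    uniform in provenance — imputed records are not down-weighted.
    Also carries the moderator/grouping columns the model needs.
    """
    df = ds.to_frame()
    n_used = df["n_couples"].to_numpy(dtype=int)
    df["zr"] = np.arctanh(df["r_observed"].to_numpy(dtype=float))
    # squared SE rather than 1/(N-3) directly, so var_zr == se_zr(N)**2
    # holds bit-for-bit
    df["var_zr"] = (1.0 / np.sqrt(n_used - 3.0)) ** 2
    df["n_used"] = n_used
    years = df["year_published"].to_numpy(dtype=float)
    df["year_centered"] = years - years.mean()
    return df


def effect_sizes(ds: Dataset) -> list[EffectSize]:
    df = compute_effects(ds)
    return [
        EffectSize(rid, float(z), float(v), int(n))
        for rid, z, v, n in zip(df["record_id"], df["zr"], df["var_zr"], df["n_used"])
    ]
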