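"""End-to-end orchestration of the published analysis sequence.

Stages, in order: validation → effect-size transforms → no-moderator
model → full model (western + mean-centered year) → interaction check
(reported, never kept in the final model) → subgroup fits → per-model
heterogeneity → rank test + funnel → figures → report serialization.
The report is deterministic given data and configuration (sorted keys,
no clock or RNG), so repeated runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .effects import compute_effects
from .heterogeneity import begg_rank_test, funnel_data, heterogeneity_report
from .model import (
    MetaFit,
    MetaModelSpec,
    fit_model,
    pooled_estimate,
    profile_likelihood_check,
    wald_test,
)
from .records import Dataset, read_studies, validation_report

log = logging.getLogger("heightmeta")

DEFAULT_CONFIG: dict[str, Any] = {
    "estimation": "REML",
    "ci_level": 0.95,
    "moderators": ["intercept", "western", "year_centered"],
    "random_factors": ["author_group", "country"],
    "begg_on_residuals": False,
    "rounding": {"n_from_se": "half_away", "n_from_p_category": "floor"},
    "profile_check": True,
}


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, val in user.items():
            if key not in cfg:
                raise KeyError(f"unknown config key {key!r}")
            if isinstance(cfg[key], dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


@dataclass
class AnalysisReport:
    counts: dict[str, int]
    model_no_moderators: dict[str, Any]
    model_full: dict[str, Any]
    interaction_check: dict[str, Any]
    subgroup_western: dict[str, Any]
    subgroup_nonwestern: dict[str, Any]
    bias: dict[str, Any]
    provenance: dict[str, Any]
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "model_no_moderators": self.model_no_moderators,
            "model_full": self.model_full,
            "interaction_check": self.interaction_check,
            "subgroup_western": self.subgroup_western,
            "subgroup_nonwestern": self.subgroup_nonwestern,
            "bias": self.bias,
            "provenance": self.provenance,
            "warnings": self.warnings,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=True)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"[{stage}] {cause}")


def _hash_bytes(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()[:16]


def _model_summary(fit: MetaFit, df: pd.DataFrame, config, q_moderators=None) -> dict:
    pooled = pooled_estimate(fit, level=config["ci_level"])
    het = heterogeneity_report(fit, df, moderators=q_moderators or fit.spec.moderators)
    coefs = {}
    for name in fit.coef_names:
        est, se = fit.coef(name)
        stat, p = wald_test(fit, name)
        coefs[name] = {"estimate": est, "se": se, "z": stat, "p": p}
    return {
        "k": fit.k,
        "pooled_r": pooled["r"],
        "ci_low": pooled["ci_low"],
        "ci_high": pooled["ci_high"],
        "pooled_z": pooled["z"],
        "se_z": pooled["se_z"],
        "coefficients": coefs,
        "sigma2": {k: float(v) for k, v in fit.sigma2.items()},
        "loglik": fit.loglik,
        "converged": fit.converged,
        "profile_ok": fit.profile_ok,
        "heterogeneity": het.to_dict(),
        "dropped_moderators": fit.dropped_moderators,
        "mean_year_used": fit.mean_year_used,
    }


def run_full_analysis(
    data: str | Path | Dataset,
    config: dict[str, Any] | None = None,
) -> tuple[AnalysisReport, dict[str, Any]]:
    """Run the whole analysis; returns the report and reusable artifacts.

    Artifacts: the effects table plus the fitted model objects and
    funnel points, for figure rendering and further inspection.
    Non-convergence of one model is recorded as a warning; independent
    stages still run.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    warnings: list[str] = []

    stage = "validate"
    try:
        if isinstance(data, Dataset):
            ds = data
            data_hash = _hash_bytes(ds.to_frame().to_csv(index=False).encode())
        else:
            raw = Path(data).read_bytes()
            data_hash = _hash_bytes(raw)
            ds = read_studies(data)
        vreport = validation_report(ds)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    log.info("validate: %d records, hash %s", len(ds), data_hash)

    stage = "transform"
    try:
        df = compute_effects(ds)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    rf = tuple(cfg["random_factors"])

    def _fit(frame, moderators, label) -> MetaFit | None:
        spec = MetaModelSpec(
            moderators=tuple(moderators), random_factors=rf, method=cfg["estimation"]
        )
        try:
            fit = fit_model(frame, spec)
        except Exception as exc:
            warnings.append(f"{label}: fit failed ({exc})")
            return None
        if not fit.converged:
            warnings.append(f"{label}: optimizer did not converge")
            return None
        if fit.dropped_moderators:
            warnings.append(f"{label}: dropped degenerate moderators {fit.dropped_moderators}")
        if cfg["profile_check"]:
            profile_likelihood_check(fit, frame)
            if not fit.profile_ok:
                warnings.append(f"{label}: likelihood profile flags possible false convergence")
        return fit

    m0 = _fit(df, ("intercept",), "model_no_moderators")
    full = _fit(df, tuple(cfg["moderators"]), "model_full")
    inter = _fit(
        df, tuple(cfg["moderators"]) + ("western:year_centered",), "interaction_check"
    )

    df_w = df[df["western"]].reset_index(drop=True)
    df_nw = df[~df["western"]].reset_index(drop=True)
    sub_w = _fit(df_w, ("intercept",), "subgroup_western") if len(df_w) > 3 else None
    sub_nw = _fit(df_nw, ("intercept",), "subgroup_nonwestern") if len(df_nw) > 3 else None

    stage = "bias"
    try:
        tau, p_tau = begg_rank_test(df, residuals_of=full if cfg["begg_on_residuals"] else None)
        bias = {"kendall_tau": float(tau), "p": float(p_tau),
                "on_residuals": bool(cfg["begg_on_residuals"])}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    funnel = funnel_data(df, m0) if m0 is not None else None

    r = df["r_observed"].to_numpy(dtype=float)
    counts = {
        "k_total": int(len(df)),
        "k_positive": int((r > 0).sum()),
        "k_negative": int((r < 0).sum()),
        "k_zero": int((r == 0).sum()),
        "n_countries": vreport["n_countries"],
        "n_western_countries": vreport["n_western_countries"],
        "n_author_groups": vreport["n_author_groups"],
    }

    def summary(fit, frame, q_mods=None):
        if fit is None:
            return {"converged": False}
        return _model_summary(fit, frame, cfg, q_moderators=q_mods)

    interaction = {"converged": False}
    if inter is not None:
        est, se = inter.coef("western:year_centered")
        _, p = wald_test(inter, "western:year_centered")
        interaction = {"estimate": est, "se": se, "p": p, "converged": True,
                       "included_in_final_model": False}

    cfg_hash = _hash_bytes(json.dumps(cfg, sort_keys=True, default=str).encode())
    report = AnalysisReport(
        counts=counts,
        model_no_moderators=summary(m0, df),
        model_full=summary(full, df),
        interaction_check=interaction,
        subgroup_western=summary(sub_w, df_w),
        subgroup_nonwestern=summary(sub_nw, df_nw),
        bias=bias,
        provenance={
            "dataset_hash": data_hash,
            "config_hash": cfg_hash,
            "software_version": __version__,
            "validation": vreport,
        },
        warnings=warnings,
    )
    artifacts = {
        "effects": df,
        "fits": {"no_moderators": m0, "full": full, "interaction": inter,
                 "western": sub_w, "nonwestern": sub_nw},
        "funnel": funnel,
    }
    return report, artifacts


def render_figures(report: AnalysisReport, effects: pd.DataFrame, outdir: str | Path) -> list[Path]:
    """Forest-style plot by region plus funnel plot, written as SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if effects.empty:
        raise ValueError("no effects to plot")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    # --- forest ---
    fig, ax = plt.subplots(figsize=(7, max(4, 0.045 * len(effects) + 2)))
    y = 0
    yticks, ylabels = [], []
    for label, flag, sub in (
        ("Western", True, report.subgroup_western),
        ("Non-western", False, report.subgroup_nonwestern),
    ):
        grp = effects[effects["western"] == flag].sort_values("r_observed")
        for _, row in grp.iterrows():
            se = np.sqrt(row["var_zr"])
            lo, hi = np.tanh(row["zr"] - 1.96 * se), np.tanh(row["zr"] + 1.96 * se)
            ax.plot([lo, hi], [y, y], color="0.6", lw=0.7)
            ax.plot(row["r_observed"], y, "o", ms=2.5, color="0.2")
            y += 1
        if sub.get("converged"):
            ax.plot(
                [sub["ci_low"], sub["pooled_r"], sub["ci_high"], sub["pooled_r"], sub["ci_low"]],
                [y, y + 0.6, y, y - 0.6, y],
                color="tab:red",
            )
            yticks.append(y)
            ylabels.append(f"{label} pooled r={sub['pooled_r']:.2f}")
        y += 3
    ax.axvline(0, color="k", lw=0.5)
    ax.set_yticks(yticks, ylabels)
    ax.set_xlabel("within-pair height correlation r")
    fig.tight_layout()
    forest = outdir / "forest.svg"
    fig.savefig(forest)
    plt.close(fig)
    written.append(forest)

    # --- funnel ---
    fig, ax = plt.subplots(figsize=(5, 4))
    se = np.sqrt(effects["var_zr"].to_numpy(dtype=float))
    ax.plot(effects["zr"], se, "o", ms=3, alpha=0.6)
    center = report.model_no_moderators.get("pooled_z")
    if center is not None:
        ax.axvline(center, color="tab:red", lw=1)
        grid = np.linspace(0, se.max(), 50)
        ax.plot(center - 1.96 * grid, grid, "--", color="0.5", lw=0.7)
        ax.plot(center + 1.96 * grid, grid, "--", color="0.5", lw=0.7)
    ax.invert_yaxis()
    ax.set_xlabel("Fisher z")
    ax.set_ylabel("standard error")
    fig.tight_layout()
    funnel = outdir / "funnel.svg"
    fig.savefig(funnel)
    plt.close(fig)
    written.append(funnel)
    return written


def summary_table(report: AnalysisReport) -> pd.DataFrame:
    """Flat TSV-ready view of the headline numbers."""
    rows = []
    for name, model in (
        ("all_studies", report.model_no_moderators),
        ("full_model", report.model_full),
        ("western", report.subgroup_western),
        ("nonwestern", report.subgroup_nonwestern),
    ):
        if not model.get("converged"):
            continue
        het = model["heterogeneity"]
        rows.append(
            {
                "model": name,
                "k": model["k"],
                "pooled_r": round(model["pooled_r"], 4),
                "ci_low": round(model["ci_low"], 4),
                "ci_high": round(model["ci_high"], 4),
                "Q": round(het["Q"], 2),
                "df": het["df"],
                "I2_pct": round(het["I2_total"], 1),
            }
        )
    return pd.DataFrame(rows)
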