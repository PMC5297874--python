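import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

import heightmeta as hm
from heightmeta.model import build_design, restricted_loglik, _factor_matrix

from conftest import make_effects_frame
import _oracles


def six_study_frame(seed=3):
    """Small crossed design: 6 studies, 2 author groups x 2 countries."""
    rng = np.random.default_rng(seed)
    return make_effects_frame(
        zr=0.25 + rng.normal(0, 0.15, 6),
        var_zr=rng.uniform(0.005, 0.05, 6),
        author=["A1", "A1", "A2", "A2", "A1", "A2"],
        country=["C1", "C2", "C1", "C2", "C2", "C1"],
    )


class TestRemlAgainstBruteForce:
    @pytest.mark.parametrize("seed", [3, 17, 42])
    def test_grid_profile_oracle_six_studies(self, seed):
        """REML optimum agrees with an exhaustive grid/profile search."""
        df = six_study_frame(seed)
        fit = hm.fit_model(df, hm.MetaModelSpec())
        X, _ = build_design(df, ("intercept",))
        Za = _factor_matrix(df, "author_group_id")
        Zc = _factor_matrix(df, "country_name")
        z = df["zr"].to_numpy()
        v = df["var_zr"].to_numpy()
        sa, sc, ll, beta = _oracles.grid_profile_reml(X, z, v, Za, Zc, upper=0.5)
        assert fit.loglik >= ll - 1e-9  # our optimum can only be better
        assert fit.loglik == pytest.approx(ll, abs=1e-4)
        assert fit.beta[0] == pytest.approx(beta[0], abs=1e-3)
        assert fit.sigma2["author_group"] == pytest.approx(sa, abs=2e-3)
        assert fit.sigma2["country"] == pytest.approx(sc, abs=2e-3)

    def test_loglik_formula_matches_error_contrast_definition(self):
        """The closed-form restricted likelihood equals the density of
        the error contrasts A'z, for arbitrary variance components."""
        df = six_study_frame(5)
        X, _ = build_design(df, ("intercept",))
        Za = _factor_matrix(df, "author_group_id")
        Zc = _factor_matrix(df, "country_name")
        z = df["zr"].to_numpy()
        v = df["var_zr"].to_numpy()
        for sa, sc in [(0.0, 0.0), (0.01, 0.0), (0.02, 0.03), (0.3, 0.001)]:
            ours = restricted_loglik([sa, sc], X, z, v, [Za, Zc])
            theirs = _oracles.contrast_reml_loglik(sa, sc, X, z, v, Za, Zc)
            assert ours == pytest.approx(theirs, abs=1e-9)


class TestFixedEffectsLimit:
    def test_symmetric_two_study_pool(self):
        df = make_effects_frame([0.2, 0.4], [0.01, 0.01])
        fit = hm.fit_model(df, hm.MetaModelSpec(random_factors=()))
        assert fit.beta[0] == pytest.approx(0.3, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_wls_closed_form_with_zero_components(self, seed):
        """With no random components beta is (X'WX)^-1 X'Wz, W=diag(N-3)."""
        rng = np.random.default_rng(seed)
        k = 25
        n = rng.integers(10, 500, k)
        df = make_effects_frame(
            zr=rng.normal(0.2, 0.3, k),
            var_zr=1.0 / (n - 3),
            western=rng.integers(0, 2, k).astype(bool).tolist(),
            year=rng.normal(0, 10, k),
        )
        fit = hm.fit_model(
            df,
            hm.MetaModelSpec(
                moderators=("intercept", "western", "year_centered"), random_factors=()
            ),
        )
        X, _ = build_design(df, ("intercept", "western", "year_centered"))
        W = np.diag(n - 3.0)
        beta_wls = linalg.solve(X.T @ W @ X, X.T @ W @ df["zr"].to_numpy())
        assert np.max(np.abs(fit.beta - beta_wls)) < 1e-10


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
class TestMetaforCrossValidation:
    def test_matches_rma_mv(self, small_effects, tmp_path):
        """External oracle: metafor's rma.mv on the same table."""
        df = small_effects
        csv = tmp_path / "d.csv"
        out = df[["zr", "var_zr", "western", "year_centered", "author_group_id", "country_name"]].copy()
        out["western"] = out["western"].astype(int)
        out.to_csv(csv, index=False)
        script = f"""
        suppressMessages(library(metafor))
        d <- read.csv("{csv}")
        m <- rma.mv(zr ~ western + year_centered, V = var_zr,
                    random = list(~1|author_group_id, ~1|country_name),
                    data = d, method = "REML")
        cat(jsonlite::toJSON(list(beta=unname(coef(m)), se=m$se,
            sigma2=m$sigma2, ll=as.numeric(logLik(m))), digits=12))
        """
        res = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert res.returncode == 0, res.stderr
        ref = json.loads(res.stdout)
        fit = hm.fit_model(
            df, hm.MetaModelSpec(moderators=("intercept", "western", "year_centered"))
        )
        assert np.allclose(fit.beta, ref["beta"], atol=1e-5)
        assert np.allclose(fit.se, ref["se"], atol=1e-5)
        assert np.allclose(
            [fit.sigma2["author_group"], fit.sigma2["country"]], ref["sigma2"], atol=1e-5
        )
        assert fit.loglik == pytest.approx(ref["ll"][0], abs=1e-5)


class TestFitContracts:
    def test_rank_deficient_design_rejected(self):
        df = make_effects_frame(
            [0.1, 0.2, 0.3, 0.25, 0.15, 0.3],
            [0.01] * 6,
            western=[True] * 3 + [False] * 3,
            year=[1.0, 1.0, 1.0, -1.0, -1.0, -1.0],
        )
        df["year_centered"] = np.where(df["western"], 1.0, -1.0)  # collinear with western
        with pytest.raises(ValueError, match="rank"):
            hm.fit_model(
                df,
                hm.MetaModelSpec(
                    moderators=("intercept", "western", "year_centered"), random_factors=()
                ),
            )

    def test_too_few_studies_rejected(self):
        df = make_effects_frame([0.1, 0.2], [0.01, 0.01], western=[True, False])
        with pytest.raises(ValueError, match="too few"):
            hm.fit_model(
                df, hm.MetaModelSpec(moderators=("intercept", "western"), random_factors=())
            )

    def test_degenerate_moderator_dropped(self):
        df = six_study_frame()
        df["western"] = True  # all-western subset
        fit = hm.fit_model(df, hm.MetaModelSpec(moderators=("intercept", "western")))
        assert fit.dropped_moderators == ["western"]
        assert fit.coef_names == ["intercept"]

    def test_order_and_relabel_invariance(self, small_effects):
        spec = hm.MetaModelSpec(moderators=("intercept", "western", "year_centered"))
        fit = hm.fit_model(small_effects, spec)
        shuffled = small_effects.sample(frac=1, random_state=99).reset_index(drop=True)
        shuffled["author_group_id"] = "grp_" + shuffled["author_group_id"]
        shuffled["country_name"] = shuffled["country_name"].str.upper()
        fit2 = hm.fit_model(shuffled, spec)
        assert np.allclose(fit.beta, fit2.beta, atol=1e-6)
        assert fit.sigma2["author_group"] == pytest.approx(fit2.sigma2["author_group"], abs=1e-6)
        assert fit.loglik == pytest.approx(fit2.loglik, abs=1e-6)

    def test_local_optimality_against_random_probes(self, small_effects):
        fit = hm.fit_model(small_effects, hm.MetaModelSpec())
        X, _ = build_design(small_effects, ("intercept",))
        Za = _factor_matrix(small_effects, "author_group_id")
        Zc = _factor_matrix(small_effects, "country_name")
        z = small_effects["zr"].to_numpy()
        v = small_effects["var_zr"].to_numpy()
        rng = np.random.default_rng(1)
        probes = rng.uniform(0, 0.2, size=(100, 2))
        lls = [restricted_loglik(s2, X, z, v, [Za, Zc]) for s2 in probes]
        assert fit.loglik >= max(lls) - 1e-8


class TestPooledEstimate:
    @staticmethod
    def _fake_fit(est, se):
        return hm.MetaFit(
            coef_names=["intercept"],
            beta=np.array([est]),
            se=np.array([se]),
            vcov=np.array([[se**2]]),
            sigma2={},
            loglik=0.0,
            method="REML",
            k=10,
            p=1,
            converged=True,
            mean_year_used=2000.0,
            spec=hm.MetaModelSpec(random_factors=()),
        )

    def test_symmetric_back_transformed_ci(self):
        out = hm.pooled_estimate(self._fake_fit(0.0, 0.1))
        assert out["r"] == 0.0
        assert out["ci_low"] == pytest.approx(-out["ci_high"], abs=1e-15)
        assert round(out["ci_high"], 3) == 0.194

    def test_degenerate_se_zero(self):
        out = hm.pooled_estimate(self._fake_fit(0.3, 0.0))
        assert out["ci_low"] == out["r"] == out["ci_high"] == pytest.approx(np.tanh(0.3))

    def test_monotone_image_of_z_ci(self):
        out = hm.pooled_estimate(self._fake_fit(0.25, 0.07))
        assert out["ci_low"] == pytest.approx(np.tanh(0.25 - 1.959963984540054 * 0.07))
        assert out["ci_high"] == pytest.approx(np.tanh(0.25 + 1.959963984540054 * 0.07))
        assert -1 < out["ci_low"] < out["r"] < out["ci_high"] < 1

    def test_refuses_nonconverged(self):
        fit = self._fake_fit(0.1, 0.1)
        fit.converged = False
        with pytest.raises(RuntimeError):
            hm.pooled_estimate(fit)


class TestWaldTest:
    def test_null_estimate(self):
        fit = TestPooledEstimate._fake_fit(0.0, 0.1)
        stat, p = hm.wald_test(fit, "intercept")
        assert stat == 0.0 and p == 1.0

    def test_quantile_and_symmetry(self):
        stat, p = hm.wald_test(TestPooledEstimate._fake_fit(0.196, 0.1), "intercept")
        assert p == pytest.approx(0.05, abs=1e-3)
        _, p_neg = hm.wald_test(TestPooledEstimate._fake_fit(-0.196, 0.1), "intercept")
        assert p == pytest.approx(p_neg, abs=1e-15)

    def test_unknown_coefficient(self):
        with pytest.raises(KeyError):
            hm.wald_test(TestPooledEstimate._fake_fit(0.1, 0.1), "western")


class TestProfileCheck:
    def test_true_optimum_passes(self, small_effects):
        fit = hm.fit_model(small_effects, hm.MetaModelSpec())
        hm.profile_likelihood_check(fit, small_effects)
        assert fit.profile_ok is True
        assert set(fit.profiles) == {"author_group", "country"}

    def test_boundary_estimate_passes(self):
        # homogeneous data push both components to the 0 boundary
        df = make_effects_frame(
            [0.2] * 8, [0.01] * 8,
            author=["A1", "A2"] * 4, country=["C1", "C1", "C2", "C2"] * 2,
        )
        fit = hm.fit_model(df, hm.MetaModelSpec())
        assert fit.sigma2["author_group"] == 0.0
        hm.profile_likelihood_check(fit, df)
        assert fit.profile_ok is True

    def test_perturbed_parameters_flagged(self, small_effects):
        fit = hm.fit_model(small_effects, hm.MetaModelSpec())
        X, _ = build_design(small_effects, ("intercept",))
        Za = _factor_matrix(small_effects, "author_group_id")
        Zc = _factor_matrix(small_effects, "country_name")
        bad = {"author_group": fit.sigma2["author_group"] * 30 + 0.5,
               "country": fit.sigma2["country"]}
        fit.sigma2 = bad
        fit.loglik = restricted_loglik(
            [bad["author_group"], bad["country"]],
            X,
            small_effects["zr"].to_numpy(),
            small_effects["var_zr"].to_numpy(),
            [Za, Zc],
        )
        hm.profile_likelihood_check(fit, small_effects)
        assert fit.profile_ok is False
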