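import numpy as np
import pytest

import heightmeta as hm

from conftest import make_effects_frame
import _oracles


class TestQStatistic:
    def test_two_study_hand_computation(self):
        # w=100 each, FE mean 0.3: Q = 100*0.01 + 100*0.01 = 2
        df = make_effects_frame([0.2, 0.4], [0.01, 0.01])
        Q, dof, p = hm.q_statistic(df)
        assert Q == pytest.approx(2.0, abs=1e-12)
        assert dof == 1

    def test_identical_effects_give_zero(self):
        df = make_effects_frame([0.3] * 5, [0.01, 0.02, 0.05, 0.1, 0.3])
        Q, _, p = hm.q_statistic(df)
        assert Q == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_order_invariance(self, small_effects):
        Q1, d1, _ = hm.q_statistic(small_effects, ("intercept", "western", "year_centered"))
        shuffled = small_effects.sample(frac=1, random_state=5).reset_index(drop=True)
        Q2, d2, _ = hm.q_statistic(shuffled, ("intercept", "western", "year_centered"))
        assert Q1 == pytest.approx(Q2, rel=1e-12)
        assert d1 == d2 == len(small_effects) - 3

    def test_needs_more_studies_than_coefficients(self):
        df = make_effects_frame([0.2], [0.01])
        with pytest.raises(ValueError):
            hm.q_statistic(df)


class TestISquared:
    @staticmethod
    def _fit_with(sigma2):
        return hm.MetaFit(
            coef_names=["intercept"],
            beta=np.array([0.2]),
            se=np.array([0.05]),
            vcov=np.array([[0.0025]]),
            sigma2=sigma2,
            loglik=0.0,
            method="REML",
            k=10,
            p=1,
            converged=True,
            mean_year_used=2000.0,
            spec=hm.MetaModelSpec(),
        )

    def test_arithmetic(self):
        # construct data whose typical v is exactly 0.01
        df = make_effects_frame([0.1] * 5, [0.01] * 5)
        fit = self._fit_with({"author_group": 0.02, "country": 0.01})
        total, by_factor, vt = hm.i_squared(fit, df)
        assert vt == pytest.approx(0.01)
        assert total == pytest.approx(75.0)
        assert by_factor["author_group"] == pytest.approx(50.0)
        assert by_factor["country"] == pytest.approx(25.0)

    def test_zero_components(self):
        df = make_effects_frame([0.1] * 5, [0.01] * 5)
        total, _, _ = hm.i_squared(self._fit_with({"author_group": 0.0, "country": 0.0}), df)
        assert total == 0.0

    def test_monotone_in_components(self):
        df = make_effects_frame([0.1] * 5, [0.01] * 5)
        vals = [
            hm.i_squared(self._fit_with({"author_group": s, "country": 0.005}), df)[0]
            for s in (0.0, 0.01, 0.05, 0.2)
        ]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_typical_v_equal_variances(self):
        # equal v: (k-1)*k*w / (k^2 w^2 - k w^2) = 1/w = v
        v = np.full(7, 0.025)
        assert hm.typical_sampling_variance(v) == pytest.approx(0.025)


class TestBeggRankTest:
    def test_perfect_monotone_association(self):
        k = 6
        v = np.linspace(0.01, 0.06, k)
        w = 1 / v
        # build z whose standardized deviations increase with v
        z = np.full(k, 0.2)
        zpool = np.sum(w * z) / w.sum()
        star_target = np.linspace(-1, 1, k)
        z = zpool + star_target * np.sqrt(v - 1 / w.sum())
        df = make_effects_frame(z, v)
        tau, _ = hm.begg_rank_test(df)
        assert tau == pytest.approx(1.0)

    def test_four_point_brute_force_oracle(self):
        df = make_effects_frame([0.35, 0.1, 0.28, -0.05], [0.01, 0.04, 0.02, 0.09])
        tau, _ = hm.begg_rank_test(df)
        z = df["zr"].to_numpy()
        v = df["var_zr"].to_numpy()
        w = 1 / v
        star = (z - np.sum(w * z) / w.sum()) / np.sqrt(v - 1 / w.sum())
        assert tau == pytest.approx(_oracles.kendall_tau_by_pairs(star, v), abs=1e-12)

    def test_negation_flips_tau_not_p(self):
        rng = np.random.default_rng(2)
        df = make_effects_frame(rng.normal(0.2, 0.2, 12), rng.uniform(0.005, 0.1, 12))
        tau, p = hm.begg_rank_test(df)
        neg = df.copy()
        neg["zr"] = -neg["zr"]
        tau_n, p_n = hm.begg_rank_test(neg)
        assert tau_n == pytest.approx(-tau, abs=1e-12)
        assert p_n == pytest.approx(p, abs=1e-12)

    def test_exact_permutation_small_k(self):
        rng = np.random.default_rng(3)
        df = make_effects_frame(rng.normal(0.2, 0.2, 6), rng.uniform(0.01, 0.1, 6))
        tau_a, p_asym = hm.begg_rank_test(df)
        tau_e, p_exact = hm.begg_rank_test(df, exact=True)
        assert tau_a == tau_e
        assert 0.0 <= p_exact <= 1.0
        with pytest.raises(ValueError):
            hm.begg_rank_test(make_effects_frame(np.zeros(9), np.full(9, 0.01)), exact=True)

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            hm.begg_rank_test(make_effects_frame([0.1, 0.2], [0.01, 0.02]))


class TestFunnelData:
    def test_cardinality_center_and_monotonicity(self, small_effects):
        fit = hm.fit_model(small_effects, hm.MetaModelSpec())
        funnel = hm.funnel_data(small_effects, fit)
        assert len(funnel) == len(small_effects)
        assert funnel.attrs["center"] == pytest.approx(fit.beta[0])
        order = np.argsort(small_effects["n_used"].to_numpy())
        se_sorted = funnel["se_zr"].to_numpy()[order]
        assert all(a >= b for a, b in zip(se_sorted, se_sorted[1:]))


class TestHeterogeneityCalibration:
    def test_zero_components_give_small_q_and_i2(self):
        """Homogeneous simulations: Q/df near 1, I2 concentrated near 0."""
        cfg = dict(n_studies=30, n_authors=15, n_countries=8,
                   sigma2_author=0.0, sigma2_country=0.0,
                   beta_western=0.0, beta_year=0.0)
        ratios, i2s = [], []
        for rep in range(200):
            ds, _ = hm.simulate_studies(hm.SimConfig(seed=50_000 + rep, **cfg))
            df = hm.compute_effects(ds)
            Q, dof, _ = hm.q_statistic(df)
            ratios.append(Q / dof)
            fit = hm.fit_model(df, hm.MetaModelSpec())
            i2s.append(hm.i_squared(fit, df)[0])
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)
        assert np.median(i2s) < 15.0

    def test_large_components_give_high_i2(self):
        """Strong clustering dominates sampling error: I2 above 90%."""
        hits = 0
        for rep in range(30):
            ds, _ = hm.simulate_studies(
                hm.SimConfig(seed=60_000 + rep, n_studies=60, n_authors=30, n_countries=12)
            )
            df = hm.compute_effects(ds)
            fit = hm.fit_model(df, hm.MetaModelSpec())
            if hm.i_squared(fit, df)[0] > 90.0:
                hits += 1
        assert hits > 15
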