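import numpy as np
import pandas as pd
import pytest

from overstride.mixedlm import (RandomInterceptModel, rmse_fc,
                                run_model_menu, variance_explained, zscore)
from overstride.simulate import simulate_lmm_dataset
from overstride.validation import em_reml_random_intercept


# small printed fixture: 3 groups x 4 observations
FIXTURE = pd.DataFrame({
    "participant_id": ["A"] * 4 + ["B"] * 4 + ["C"] * 4,
    "x": [-1.0, 0.0, 1.0, 2.0, -2.0, -1.0, 0.0, 1.0, 0.0, 1.0, 2.0, 3.0],
    "y": [0.9, 2.1, 2.9, 4.2, -0.5, 0.6, 1.4, 2.6, 2.2, 3.1, 4.0, 5.3],
})


class TestZscore:
    def test_basic(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        out, params = zscore(df, ["a"])
        np.testing.assert_allclose(out["a"], [-1, 0, 1])
        assert params["a"] == (2.0, 1.0)

    def test_idempotent_on_standardized(self):
        df = pd.DataFrame({"a": [-1.0, 0.0, 1.0]})
        out, _ = zscore(df, ["a"])
        np.testing.assert_allclose(out["a"], df["a"], atol=1e-12)

    def test_round_trip(self, rng):
        from overstride.mixedlm import zscore_inverse
        df = pd.DataFrame({"a": rng.normal(3, 7, 50)})
        out, params = zscore(df, ["a"])
        np.testing.assert_allclose(zscore_inverse(out, params)["a"],
                                   df["a"], atol=1e-12)

    def test_zero_variance_named(self):
        with pytest.raises(ValueError, match="flat"):
            zscore(pd.DataFrame({"flat": [1.0, 1.0]}), ["flat"])


class TestFit:
    def test_perfect_two_group_fit(self):
        # groups y=x and y=x+1: slope exactly 1, zero residual variance
        df = pd.DataFrame({
            "participant_id": ["A"] * 3 + ["B"] * 3,
            "x": [-1.0, 0.0, 1.0] * 2,
            "y": [-1.0, 0.0, 1.0, 0.0, 1.0, 2.0],
        })
        r = RandomInterceptModel.from_dataframe(df, "y", ["x"]).fit()
        assert r.params["x"] == pytest.approx(1.0, abs=1e-10)
        assert r.sigma2_e == pytest.approx(0.0, abs=1e-5)

    def test_single_group_reduces_to_ols(self, rng):
        n = 40
        x = rng.normal(size=(n, 2))
        y = 1.5 + x @ [0.4, -0.7] + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"x1": x[:, 0], "x2": x[:, 1], "y": y,
                           "participant_id": "only"})
        r = RandomInterceptModel.from_dataframe(df, "y", ["x1", "x2"]).fit()
        Xd = np.column_stack([np.ones(n), x])
        beta_ols = np.linalg.lstsq(Xd, y, rcond=None)[0]
        np.testing.assert_allclose(r.params.to_numpy(), beta_ols, atol=1e-8)
        assert r.sigma2_b == 0.0

    def test_matches_em_reml_oracle_on_fixture(self):
        r = RandomInterceptModel.from_dataframe(FIXTURE, "y", ["x"]).fit()
        X = np.column_stack([np.ones(len(FIXTURE)), FIXTURE["x"]])
        beta, s2b, s2e = em_reml_random_intercept(
            FIXTURE["y"].to_numpy(), X, FIXTURE["participant_id"].to_numpy())
        np.testing.assert_allclose(r.params.to_numpy(), beta, atol=1e-6)
        assert r.sigma2_b == pytest.approx(s2b, abs=1e-6)
        assert r.sigma2_e == pytest.approx(s2e, abs=1e-6)

    def test_matches_statsmodels_mixedlm(self, rng):
        import statsmodels.formula.api as smf
        df = simulate_lmm_dataset([0.5, -0.3], 0.8, 0.4, 8, 20, rng)
        r = RandomInterceptModel.from_dataframe(df, "y", ["x1", "x2"]).fit()
        sm = smf.mixedlm("y ~ x1 + x2", df,
                         groups=df["participant_id"]).fit(reml=True)
        np.testing.assert_allclose(
            r.params.to_numpy(),
            sm.params[["Intercept", "x1", "x2"]].to_numpy(), atol=1e-4)
        assert r.sigma2_e == pytest.approx(sm.scale, abs=1e-4)
        assert r.sigma2_b == pytest.approx(float(sm.cov_re.iloc[0, 0]),
                                           abs=1e-3)

    def test_boundary_sigma_b_zero(self, rng):
        import warnings
        df = simulate_lmm_dataset([0.6], 0.0, 0.5, 10, 30, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # boundary warning is expected
            r = RandomInterceptModel.from_dataframe(df, "y", ["x1"]).fit()
        assert r.icc < 0.05

    def test_blups_shrink_group_means(self, rng):
        df = simulate_lmm_dataset([0.5], 1.0, 0.3, 6, 40, rng)
        r = RandomInterceptModel.from_dataframe(df, "y", ["x1"]).fit()
        resid = df["y"] - r.fitted_fixed
        raw = resid.groupby(df["participant_id"]).mean()
        # BLUPs lie between 0 and the raw group residual means
        for g in raw.index:
            assert 0 <= r.random_effects[g] / raw[g] <= 1.0

    def test_summary_mentions_components(self):
        r = RandomInterceptModel.from_dataframe(FIXTURE, "y", ["x"]).fit()
        s = r.summary()
        assert "ICC" in s and "Marginal R2" in s and "x" in s


class TestVarianceExplained:
    def test_closed_form(self):
        class Dummy:
            sigma2_f, sigma2_b, sigma2_e = 2.0, 1.0, 1.0
        assert variance_explained(Dummy()) == (0.5, 0.75)

    def test_no_random_variance_marginal_equals_conditional(self):
        class Dummy:
            sigma2_f, sigma2_b, sigma2_e = 2.0, 0.0, 1.0
        m, c = variance_explained(Dummy())
        assert m == c

    def test_recovery_against_generative_ratios(self, rng):
        beta = np.array([0.6, 0.6, 0.05])
        s2b, s2e = 1.0, 0.09
        df = simulate_lmm_dataset(beta, np.sqrt(s2b), np.sqrt(s2e), 10, 75,
                                  rng)
        r = RandomInterceptModel.from_dataframe(
            df, "y", ["x1", "x2", "x3"]).fit()
        s2f = float(beta @ beta)  # X iid standard normal
        tot = s2f + s2b + s2e
        m, c = variance_explained(r)
        assert m == pytest.approx(s2f / tot, abs=0.06)
        assert c == pytest.approx((s2f + s2b) / tot, abs=0.06)


class TestRmse:
    def _table(self, delta):
        n = 50
        base = np.linspace(0, 10, n)
        d = {}
        for seg in ("thigh", "shank", "foot"):
            d[f"theta_{seg}_fc"] = base
            d[f"theta_{seg}_imu_fc"] = base + delta
        return pd.DataFrame(d)

    def test_identical_zero(self):
        assert rmse_fc(self._table(0.0)).max() == 0.0

    def test_constant_offset(self):
        np.testing.assert_allclose(rmse_fc(self._table(3.0)), 3.0)

    def test_iid_noise_chi_scaling(self, rng):
        n = 750
        t = {}
        for seg in ("thigh", "shank", "foot"):
            t[f"theta_{seg}_fc"] = np.zeros(n)
            t[f"theta_{seg}_imu_fc"] = rng.normal(0, 3.0, n)
        out = rmse_fc(pd.DataFrame(t))
        assert np.all(np.abs(out - 3.0) < 0.25)


class TestMenu:
    def test_menu_on_generated_stride_table(self, rng):
        # two-condition table with known coupling
        rows = []
        for pid in range(6):
            for cond in ("TM_SF80", "TM_SF90", "OG"):
                th = rng.normal(20, 2, 20)
                sh = rng.normal(8, 2, 20)
                ft = rng.normal(12, 3, 20)
                os_n = 0.4 * np.sin(np.radians(th)) + \
                    0.4 * np.sin(np.radians(sh)) + pid * 0.01
                pbf = (0.3 + 0.01 * th + 0.01 * sh + 0.005 * ft
                       + pid * 0.02 + rng.normal(0, 0.01, 20))
                rows.append(pd.DataFrame({
                    "participant_id": f"P{pid}", "condition": cond,
                    "theta_thigh_fc": th, "theta_shank_fc": sh,
                    "theta_foot_fc": ft,
                    "theta_thigh_imu_fc": th + rng.normal(0, 2, 20),
                    "theta_shank_imu_fc": sh + rng.normal(0, 2, 20),
                    "theta_foot_imu_fc": ft + rng.normal(0, 2, 20),
                    "overstriding_norm": os_n, "pbf_bw": pbf,
                    "duty_cycle": rng.normal(0.3, 0.01, 20)}))
        table = pd.concat(rows, ignore_index=True)
        fits = run_model_menu(table)
        assert set(fits) == {"1A", "2A", "3A", "4A", "1B", "2B", "3B", "4B"}
        for fit in fits.values():
            assert fit.converged
            m, c = variance_explained(fit)
            assert 0 <= m <= c <= 1
        # mocap models explain more marginal variance than noisy IMU models
        assert fits["1A"].r2_marginal > fits["1B"].r2_marginal
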