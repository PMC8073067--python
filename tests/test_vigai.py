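import datetime as dt

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from satgai.vigai import (
    GaiModel,
    SENTINEL2_MODELS,
    compute_vi,
    date_effect_test,
    fit_gai_model,
    mae,
    predict_gai,
    r_squared,
)


def loop_mae(pred, obs):
    total = 0.0
    for p, o in zip(pred, obs):
        total += abs(p - o)
    return total / len(pred)


def loop_r2_standard(pred, obs):
    obar = sum(obs) / len(obs)
    ss_res = sum((o - p) ** 2 for p, o in zip(pred, obs))
    ss_tot = sum((o - obar) ** 2 for o in obs)
    return 1 - ss_res / ss_tot


def loop_r2_as_printed(pred, obs):
    ybar = sum(pred) / len(pred)
    num = sum((p - ybar) ** 2 for p in pred)
    den = sum((o - ybar) ** 2 for o in obs)
    return num / den


class TestComputeVi:
    @pytest.mark.parametrize(
        "vi,bands,expected",
        [
            ("ndvi", {"nir": 0.5, "red": 0.1}, 0.4 / 0.6),
            ("rendvi", {"nir": 0.3, "red_edge": 0.3}, 0.0),
            ("evi2", {"nir": 0.4, "red": 0.08}, 2.5 * 0.32 / 1.592),
            ("nir_re", {"nir": 0.45, "red_edge": 0.30}, 1.5),
            ("nir_green", {"nir": 0.44, "green": 0.11}, 4.0),
            ("nir_red", {"nir": 0.36, "red": 0.09}, 4.0),
        ],
    )
    def test_formulas(self, vi, bands, expected):
        assert compute_vi(bands, vi) == pytest.approx(expected, abs=1e-12)

    def test_viquo_stacks_three_ratios(self):
        out = compute_vi(
            {"green": 0.1, "red": 0.05, "red_edge": 0.25, "nir": 0.5}, "viquo"
        )
        assert out.shape == (3,)
        np.testing.assert_allclose(out, [5.0, 10.0, 2.0])

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            compute_vi({"nir": 0.5, "green": 0.0}, "nir_green")

    def test_missing_band_raises(self):
        with pytest.raises(KeyError):
            compute_vi({"nir": 0.5}, "ndvi")

    def test_negative_reflectance_rejected(self):
        with pytest.raises(ValueError):
            compute_vi({"nir": 0.5, "red": -0.1}, "ndvi")

    def test_arrays_supported(self):
        out = compute_vi({"nir": np.array([0.4, 0.5]), "red": np.array([0.1, 0.1])}, "ndvi")
        np.testing.assert_allclose(out, [0.6, 2 / 3])


class TestPredictGai:
    def test_published_nir_re_model(self):
        assert predict_gai(SENTINEL2_MODELS["nir_re"], 1.5) == pytest.approx(3.287)

    def test_exponential_model_at_zero_vi(self):
        assert predict_gai(SENTINEL2_MODELS["ndvi"], 0.0) == pytest.approx(0.09)

    def test_clip_negative(self):
        m = GaiModel("linear_sr", {"a": -1.0, "b": 1.0}, "nir_re", clip_negative=True)
        assert predict_gai(m, 0.8) == 0.0
        raw = GaiModel("linear_sr", {"a": -1.0, "b": 1.0}, "nir_re")
        assert predict_gai(raw, 0.8) == pytest.approx(-0.2)

    def test_viquo_combination(self):
        m = SENTINEL2_MODELS["viquo"]
        sr = np.array([2.0, 3.0, 1.5])
        expected = -9.236087 - 0.023062 * 2 - 0.002741 * 3 + 8.142750 * 1.5
        assert predict_gai(m, sr) == pytest.approx(expected)

    def test_additive_exponential_variant(self):
        m = GaiModel(
            "exponential", {"a": 0.1, "b": 2.0}, "ndvi", exponential_additive=True
        )
        assert predict_gai(m, 0.5) == pytest.approx(0.1 + np.exp(1.0))

    def test_coefficient_form_mismatch(self):
        with pytest.raises(ValueError):
            GaiModel("linear_multi", {"a": 1, "b": 2}, "viquo")

    @given(
        b=st.floats(0.1, 10),
        a=st.floats(-5, 5),
        v1=st.floats(0.0, 3.0),
        dv=st.floats(0.0, 2.0),
    )
    def test_monotone_in_vi_for_positive_slope(self, b, a, v1, dv):
        for form in ("linear_sr", "exponential"):
            m = GaiModel(form, {"a": abs(a) + 0.01 if form == "exponential" else a, "b": b}, "x")
            assert predict_gai(m, v1 + dv) >= predict_gai(m, v1)


class TestMetrics:
    def test_mae_hand_example(self):
        assert mae([1, 2], [1.5, 2.5]) == pytest.approx(0.5)
        assert mae([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert mae([1, 3], [2, 5]) == mae([2, 5], [1, 3])

    def test_mae_errors(self):
        with pytest.raises(ValueError):
            mae([1], [1, 2])
        with pytest.raises(ValueError):
            mae([], [])

    def test_r2_identical_vectors(self):
        x = [0.0, 1.0, 2.0]
        assert r_squared(x, x, "standard") == pytest.approx(1.0)
        assert r_squared(x, x, "as_printed") == pytest.approx(1.0)

    def test_r2_as_printed_hand_example(self):
        obs = [0.0, 1.0, 2.0]
        pred = [0.1, 1.0, 1.9]
        assert r_squared(pred, obs, "as_printed") == pytest.approx(
            loop_r2_as_printed(pred, obs), abs=1e-12
        )

    def test_r2_constant_observations_undefined(self):
        with pytest.raises(ValueError):
            r_squared([1.0, 2.0], [1.0, 1.0], "standard")

    def test_metrics_match_loop_oracles_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = rng.integers(2, 100)
            obs = rng.normal(2, 1, n)
            pred = obs + rng.normal(0, 0.5, n)
            assert mae(pred, obs) == pytest.approx(loop_mae(pred, obs), abs=1e-12)
            assert r_squared(pred, obs, "standard") == pytest.approx(
                loop_r2_standard(pred, obs), abs=1e-12
            )
            assert r_squared(pred, obs, "as_printed") == pytest.approx(
                loop_r2_as_printed(pred, obs), abs=1e-12
            )

    def test_as_printed_equals_standard_for_ols_fit(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(1, 3, 200)
        obs = -9.781 + 8.712 * x + rng.normal(0, 0.5, 200)
        slope, intercept = np.polyfit(x, obs, 1)
        pred = intercept + slope * x
        assert r_squared(pred, obs, "as_printed") == pytest.approx(
            r_squared(pred, obs, "standard"), abs=1e-9
        )


class TestFitGaiModel:
    def test_noiseless_linear_recovery_is_exact(self):
        v = np.linspace(1.0, 2.0, 30)
        g = 1.0 + 2.0 * v
        res = fit_gai_model(v, g, "linear_sr", "nir_re")
        assert res.model.coefficients["a"] == pytest.approx(1.0, abs=1e-9)
        assert res.model.coefficients["b"] == pytest.approx(2.0, abs=1e-9)
        assert res.mae == pytest.approx(0.0, abs=1e-9)
        assert res.r2 == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "form,coef",
        [
            ("linear_sr", {"a": -9.781, "b": 8.712}),
            ("exponential", {"a": 0.09, "b": 4.1858}),
            ("linear_multi", {"a": -9.2, "b": -0.02, "c": -0.003, "d": 8.14}),
        ],
    )
    def test_noiseless_recovery_all_forms(self, form, coef):
        rng = np.random.default_rng(2)
        if form == "linear_multi":
            v = rng.uniform(1, 4, (200, 3))
        elif form == "exponential":
            v = rng.uniform(0.1, 0.9, 200)
        else:
            v = rng.uniform(1.1, 2.0, 200)
        g = np.asarray(predict_gai(GaiModel(form, coef, "x"), v))
        res = fit_gai_model(v, g, form)
        for k, true in coef.items():
            assert res.model.coefficients[k] == pytest.approx(true, rel=1e-5, abs=1e-6)

    def test_noisy_recovery_within_three_se(self):
        rng = np.random.default_rng(123)
        n = 500
        v = rng.uniform(1.1, 2.0, n)
        g = -9.781 + 8.712 * v + rng.normal(0, 0.3, n)
        res = fit_gai_model(v, g, "linear_sr", "nir_re")
        # standard errors of the OLS coefficients
        X = np.column_stack([np.ones(n), v])
        sigma2 = np.sum(res.residuals**2) / (n - 2)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        assert abs(res.model.coefficients["a"] - (-9.781)) < 3 * se[0]
        assert abs(res.model.coefficients["b"] - 8.712) < 3 * se[1]

    def test_degenerate_predictor_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_gai_model(np.ones(50), np.linspace(1, 2, 50), "linear_sr")

    def test_insufficient_n_raises(self):
        with pytest.raises(ValueError):
            fit_gai_model(np.array([1.0, 2.0]), np.array([1.0, 2.0]), "linear_sr")


class TestDateEffect:
    @staticmethod
    def simulate(slopes, n=200, sigma=0.2, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i, b in enumerate(slopes):
            v = rng.uniform(1.1, 2.1, n)
            g = -9.781 + b * v + rng.normal(0, sigma, n)
            date = dt.date(2019, 4, 1) + dt.timedelta(days=10 * i)
            rows += [(vi, gai, date) for vi, gai in zip(v, g)]
        return rows

    def test_null_equal_slopes_not_significant(self):
        report = date_effect_test(self.simulate([8.712, 8.712], seed=0))
        assert not report.significant
        assert report.n_groups == 1

    def test_different_slopes_detected(self):
        report = date_effect_test(self.simulate([8.0, 12.0], seed=1))
        assert report.significant
        assert report.n_groups == 2
        assert report.p_value < 1e-6

    def test_single_date_raises(self):
        with pytest.raises(ValueError):
            date_effect_test(self.simulate([8.0]))

    def test_too_few_records_per_date_raises(self):
        rows = self.simulate([8.0, 9.0], n=2)
        with pytest.raises(ValueError):
            date_effect_test(rows)

    def test_common_slope_close_to_shared_truth_under_null(self):
        report = date_effect_test(self.simulate([8.712, 8.712], seed=2))
        assert report.common_slope == pytest.approx(8.712, abs=0.1)

    def test_letter_groups_never_exceed_dates(self):
        report = date_effect_test(self.simulate([8.0, 10.0, 12.0], n=100, seed=4))
        assert report.n_groups <= 3
        assert set(report.letters) == set(report.slopes["date"])

    def test_matches_statsmodels_interaction_anova(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        import pandas as pd

        rows = self.simulate([8.0, 9.0, 10.5], n=60, sigma=0.4, seed=9)
        df = pd.DataFrame(rows, columns=["vi", "gai", "date"])
        df["date"] = df["date"].astype(str)
        add = smf.ols("gai ~ C(date) + vi", data=df).fit()
        full = smf.ols("gai ~ C(date) * vi", data=df).fit()
        table = anova_lm(add, full)
        report = date_effect_test(rows)
        assert report.f_stat == pytest.approx(float(table["F"].iloc[1]), rel=1e-8)
        assert report.p_value == pytest.approx(float(table["Pr(>F)"].iloc[1]), abs=1e-10)
        # per-date slopes equal the interaction-model slopes
        for date, grp in df.groupby("date"):
            i = list(report.slopes["date"].astype(str)).index(date)
            fit = np.polyfit(grp["vi"], grp["gai"], 1)
            assert report.slopes["slope"].iloc[i] == pytest.approx(fit[0], rel=1e-8)
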