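import numpy as np
import pandas as pd
import pytest

from topothought import (
    RankDeficientDesign,
    decompose_speed_effect,
    fit_ridge,
    fit_standardized_ols,
)


def _frame(seed=0, n=200, betas=(0.5, -0.3), noise=1.0, corr=0.0):
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    x2 = corr * x1 + np.sqrt(1 - corr**2) * rng.normal(size=n)
    y = betas[0] * x1 + betas[1] * x2 + noise * rng.normal(size=n)
    return pd.DataFrame({"y": y, "x1": x1, "x2": x2})


class TestOLS:
    def test_perfect_correlation(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = 2.0 * df["x"]
        res = fit_standardized_ols(df, "y", ["x"])
        assert res.coef("x") == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_orthogonal_predictors_match_normal_equations(self):
        # with predictors orthogonal to each other and to the constant, each
        # standardized coefficient is the sample covariance of z-scored y
        # with the z-scored predictor (normal equations decouple)
        rng = np.random.default_rng(3)
        n = 64
        q, _ = np.linalg.qr(np.column_stack([np.ones(n), rng.normal(size=(n, 2))]))
        x = q[:, 1:] * np.sqrt(n - 1)  # centered, orthogonal, sample sd exactly 1
        y = 0.4 * x[:, 0] - 0.2 * x[:, 1] + rng.normal(size=n)
        df = pd.DataFrame({"y": y, "x1": x[:, 0], "x2": x[:, 1]})
        ys = (y - y.mean()) / y.std(ddof=1)
        res = fit_standardized_ols(df, "y", ["x1", "x2"])
        for i, name in enumerate(["x1", "x2"]):
            expected = (ys * x[:, i]).sum() / (n - 1)
            assert res.coef(name) == pytest.approx(expected, rel=1e-8)

    def test_independent_noise_gives_null_coefficients(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(
            {"y": rng.normal(size=1000), "x1": rng.normal(size=1000),
             "x2": rng.normal(size=1000)}
        )
        res = fit_standardized_ols(df, "y", ["x1", "x2"])
        for name in ("x1", "x2"):
            assert abs(res.coef(name)) < 3 * res.params.loc[name, "se"]

    def test_residual_orthogonality_and_adj_r2_identity(self):
        df = _frame(seed=5, corr=0.4)
        res = fit_standardized_ols(df, "y", ["x1", "x2"])
        ys = (df["y"] - df["y"].mean()) / df["y"].std(ddof=1)
        fitted = res.extra["intercept"]
        for name in ("x1", "x2"):
            xs = (df[name] - df[name].mean()) / df[name].std(ddof=1)
            fitted = fitted + res.coef(name) * xs
        resid = ys - fitted
        for name in ("x1", "x2"):
            xs = (df[name] - df[name].mean()) / df[name].std(ddof=1)
            assert abs(resid @ xs) / len(df) < 1e-8
        n, p = res.n, res.n_params - 1
        assert res.adj_r2 == pytest.approx(1 - (1 - res.r2) * (n - 1) / (n - p - 1))
        t = res.params["coef"] / res.params["se"]
        np.testing.assert_allclose(np.abs(t), np.abs(res.params["t"]))

    def test_fixed_effects_reference_level(self):
        df = _frame(seed=8, n=120)
        df["group"] = np.tile(["b", "a", "c"], 40)
        res = fit_standardized_ols(df, "y", ["x1"], fixed_effects=["group"])
        # first sorted level 'a' is the reference: only b and c indicators
        assert "group[b]" in res.params.index and "group[c]" in res.params.index
        assert "group[a]" not in res.params.index

    def test_rank_deficiency_names_aliased_columns(self):
        df = _frame(seed=9)
        df["x3"] = df["x1"] * 1.0
        with pytest.raises(RankDeficientDesign) as exc:
            fit_standardized_ols(df, "y", ["x1", "x2", "x3"])
        assert {"x1", "x3"} & set(exc.value.aliased)

    def test_missing_rows_dropped_with_count(self):
        df = _frame(seed=10, n=50)
        df.loc[3, "x1"] = np.nan
        res = fit_standardized_ols(df, "y", ["x1", "x2"])
        assert res.n == 49 and res.extra["n_dropped_rows"] == 1


class TestRidge:
    def test_zero_penalty_reproduces_ols(self):
        df = _frame(seed=1, corr=0.3)
        ols = fit_standardized_ols(df, "y", ["x1", "x2"])
        ridge = fit_ridge(df, "y", ["x1", "x2"], penalty_grid=[0.0])
        for name in ("x1", "x2"):
            assert ridge.coef(name) == pytest.approx(ols.coef(name), abs=1e-8)

    def test_infinite_penalty_shrinks_to_zero(self):
        df = _frame(seed=2)
        res = fit_ridge(df, "y", ["x1", "x2"], penalty_grid=[1e12])
        assert abs(res.coef("x1")) < 1e-6 and abs(res.coef("x2")) < 1e-6

    def test_duplicated_predictor_splits_weight_equally(self):
        df = _frame(seed=3)
        df["x1b"] = df["x1"]
        lone = fit_ridge(df, "y", ["x1", "x2"], penalty_grid=[10.0])
        dup = fit_ridge(df, "y", ["x1", "x1b", "x2"], penalty_grid=[10.0])
        assert dup.coef("x1") == pytest.approx(dup.coef("x1b"), rel=1e-10)

    def test_cv_selection_is_deterministic_and_sane(self):
        df = _frame(seed=4, n=300, corr=0.9, noise=2.0)
        a = fit_ridge(df, "y", ["x1", "x2"], seed=7)
        b = fit_ridge(df, "y", ["x1", "x2"], seed=7)
        assert a.extra["penalty"] == b.extra["penalty"]
        assert np.isfinite(a.r2)


class TestDecomposition:
    def _table(self, seed, driver):
        rng = np.random.default_rng(seed)
        n = 600
        vol = rng.normal(size=n)
        ms = rng.normal(size=n)
        circ = rng.normal(size=n)
        drivers = {"min_speed": ms, "circuitousness": circ}
        y = 0.3 * vol - 0.4 * drivers[driver] + 0.5 * rng.normal(size=n)
        return pd.DataFrame(
            {
                "gpa": y,
                "z_log_norm_volume": vol,
                "z_log_speed": (ms + circ) / np.sqrt(2),
                "z_log_min_required_speed": ms,
                "z_log_circuitousness": circ,
            }
        )

    def test_min_speed_driven_outcome(self):
        table = self._table(1, "min_speed")
        m1, m2 = decompose_speed_effect(table, "gpa")
        assert abs(m2.coef("z_log_circuitousness")) < 3 * m2.params.loc[
            "z_log_circuitousness", "se"
        ]
        # standardized slope: raw slope scaled by sd(y)
        expected = -0.4 / table["gpa"].std(ddof=1)
        assert m2.coef("z_log_min_required_speed") == pytest.approx(expected, abs=0.07)
        # the combined model sees the diluted effect through speed
        assert m1.coef("z_log_speed") < 0

    def test_circuitousness_driven_outcome(self):
        table = self._table(2, "circuitousness")
        _, m2 = decompose_speed_effect(table, "gpa")
        assert abs(m2.coef("z_log_min_required_speed")) < 3 * m2.params.loc[
            "z_log_min_required_speed", "se"
        ]
        expected = -0.4 / table["gpa"].std(ddof=1)
        assert m2.coef("z_log_circuitousness") == pytest.approx(expected, abs=0.07)

    def test_reports_both_models(self):
        m1, m2 = decompose_speed_effect(self._table(3, "min_speed"), "gpa")
        assert "z_log_speed" in m1.params.index
        assert {"z_log_min_required_speed", "z_log_circuitousness"} <= set(m2.params.index)
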