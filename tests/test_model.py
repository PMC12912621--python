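import numpy as np
import pandas as pd
import pytest

from agmi.model import (GamLite, GmiAdjuster, RankDeficiencyError, apply_agmi,
                        cross_validate_estimator, evaluate, fit_gam_lite,
                        fit_ols, load_default_model, make_model_rows,
                        subgroup_evaluate)
from conftest import pairs_from_records


def ols_normal_equations(X, y):
    """Brute-force oracle: solve (A'A) b = A'y with an explicit inverse."""
    a = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(a.T @ a, a.T @ y)


class TestMakeModelRows:
    def test_row_counts_and_prior_columns(self):
        g = 3.31 + 0.02392 * 163.0
        rec = [("A", j, pd.Timestamp("2021-01-01") + pd.Timedelta(days=120 * j),
                g + 0.6, 163.0) for j in range(3)]
        rec += [("B", 0, "2021-01-01", g - 0.2, 163.0),
                ("B", 1, "2021-06-01", g, 163.0)]
        rows = make_model_rows(pairs_from_records(rec))
        assert len(rows) == 3  # (3-1) + (2-1)
        b = rows[rows.subject_id == "B"].iloc[0]
        assert b["prior_discordance"] == pytest.approx(-0.2)
        assert b["last_hba1c"] == pytest.approx(g - 0.2)


class TestGmiAdjuster:
    def test_noiseless_interpolation_is_exact(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 20).reshape(-1, 1)
        y = 2.0 + 3.0 * x[:, 0]
        fit = GmiAdjuster().fit(x, y)
        assert fit.intercept_ == pytest.approx(2.0, abs=1e-10)
        assert fit.coef_[0] == pytest.approx(3.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(8, 40))
            p = int(rng.integers(1, 4))
            x = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            fit = GmiAdjuster().fit(x, y)
            ref = ols_normal_equations(x, y)
            assert np.allclose([fit.intercept_, *fit.coef_], ref, atol=1e-8)

    def test_standard_errors_match_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(1)
        x = rng.normal(size=(60, 3))
        y = 1.0 + x @ [0.5, -0.2, 0.1] + rng.normal(0, 0.3, 60)
        fit = GmiAdjuster().fit(x, y)
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        assert np.allclose([fit.intercept_, *fit.coef_], ref.params, atol=1e-10)
        assert np.allclose(fit.se_, ref.bse, atol=1e-10)

    def test_rank_deficiency_names_columns(self):
        x = pd.DataFrame({"gmi": [7.0, 7.1, 7.2, 7.3, 7.4, 7.5],
                          "dup": [7.0, 7.1, 7.2, 7.3, 7.4, 7.5]})
        with pytest.raises(RankDeficiencyError, match="dup|gmi"):
            GmiAdjuster().fit(x, np.arange(6.0))

    def test_sklearn_contract(self):
        est = GmiAdjuster()
        assert est.get_params() == {"include_covariates": False}
        est.set_params(include_covariates=True)
        assert est.include_covariates

    def test_parameter_recovery_within_3_se(self):
        rng = np.random.default_rng(7)
        beta = np.array([-0.447, 0.913, 0.519, 0.148])
        n = 1000
        gmi = rng.normal(7.2, 0.7, n)
        prior_d = rng.normal(0, 0.48, n)
        last = gmi + rng.normal(0, 0.3, n) + prior_d
        x = np.column_stack([gmi, prior_d, last])
        y = beta[0] + x @ beta[1:] + rng.normal(0, 0.1, n)
        fit = GmiAdjuster().fit(x, y)
        est = np.array([fit.intercept_, *fit.coef_])
        assert np.all(np.abs(est - beta) <= 3 * fit.se_)


class TestApplyAgmi:
    def test_identity_coefficients_reproduce_gmi(self):
        model = {"beta0": 0.0, "beta1": 1.0, "beta2": 0.0, "beta3": 0.0}
        rng = np.random.default_rng(3)
        gmi = rng.uniform(5, 12, 1000)
        out = apply_agmi(gmi, rng.normal(size=1000), rng.uniform(5, 12, 1000), model)
        assert np.array_equal(out, gmi)

    def test_published_coefficients(self):
        model = load_default_model()
        assert (model["beta0"], model["beta1"], model["beta2"], model["beta3"]) == \
            (-0.447, 0.913, 0.519, 0.148)
        got = apply_agmi(7.209, 0.091, 7.3, model)
        expect = -0.447 + 0.913 * 7.209 + 0.519 * 0.091 + 0.148 * 7.3
        assert got == pytest.approx(expect, abs=1e-12)
        assert got == pytest.approx(7.2624, abs=1e-3)
        assert apply_agmi(0.0, 0.0, 0.0, model) == pytest.approx(-0.447)

    def test_accepts_fitted_estimator(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(50, 3))
        y = 1.0 + x @ [1.0, 0.5, 0.1] + rng.normal(0, 0.05, 50)
        fit = GmiAdjuster().fit(x, y)
        got = apply_agmi(x[:, 0], x[:, 1], x[:, 2], fit)
        assert np.allclose(got, fit.predict(x))


class TestEvaluate:
    def test_perfect_and_shifted(self):
        y = np.array([6.0, 7.0, 8.0, 9.0])
        res = evaluate(y, y)
        assert (res.r, res.r2, res.mae) == (1.0, 1.0, 0.0)
        res = evaluate(y, y + 0.5)
        assert res.r == pytest.approx(1.0)
        assert res.mae == pytest.approx(0.5)

    def test_r2_is_squared_pearson(self):
        rng = np.random.default_rng(2)
        yhat = rng.normal(size=200)
        y = 0.83 * yhat + rng.normal(size=200) * np.sqrt(1 - 0.83 ** 2)
        res = evaluate(yhat, y)
        assert res.r2 == pytest.approx(res.r ** 2, rel=1e-12)

    def test_mae_shift_and_scale_behaviour(self):
        rng = np.random.default_rng(4)
        yhat, y = rng.normal(size=50), rng.normal(size=50)
        base = evaluate(yhat, y).mae
        assert evaluate(yhat + 3, y + 3).mae == pytest.approx(base, rel=1e-12)
        assert evaluate(2 * yhat, 2 * y).mae == pytest.approx(2 * base, rel=1e-12)

    def test_degenerate_variance_signalled(self):
        with pytest.raises(ValueError):
            evaluate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSubgroups:
    def test_empty_subgroups_noticed(self):
        rows = pd.DataFrame({"subject_id": ["A"] * 5, "gmi": np.linspace(7, 8, 5),
                             "prior_discordance": np.zeros(5),
                             "last_hba1c": np.linspace(7, 8, 5),
                             "hba1c": np.linspace(7, 8, 5)})
        out = subgroup_evaluate(rows, load_default_model())
        assert "notice" in out["positive"] and "notice" in out["negative"]

    def test_adjustment_helps_when_offsets_persist(self, model_rows):
        fit = fit_ols(model_rows)
        out = subgroup_evaluate(model_rows, fit)
        for g in ("positive", "negative"):
            assert out[g]["adjusted"]["mae"] < out[g]["unadjusted"]["mae"]


class TestCrossValidation:
    def test_deterministic_under_seed(self, model_rows):
        a = cross_validate_estimator(model_rows, GmiAdjuster(), 5, seed=9)
        b = cross_validate_estimator(model_rows, GmiAdjuster(), 5, seed=9)
        assert a == b

    def test_subject_level_folds(self, model_rows):
        from agmi.model import _subject_folds
        rng = np.random.default_rng(0)
        subjects = model_rows["subject_id"].to_numpy()
        folds = _subject_folds(subjects, 5, rng)
        df = pd.DataFrame({"s": subjects, "f": folds})
        assert (df.groupby("s")["f"].nunique() == 1).all()


class TestGamLite:
    @staticmethod
    def linear_rows(n=800, seed=0):
        rng = np.random.default_rng(seed)
        gmi = rng.normal(7.2, 0.7, n)
        prior_d = rng.normal(0, 0.5, n)
        last = gmi + prior_d + rng.normal(0, 0.3, n)
        y = -0.4 + 0.9 * gmi + 0.5 * prior_d + 0.15 * last + rng.normal(0, 0.2, n)
        return pd.DataFrame({"subject_id": [f"S{i // 3}" for i in range(n)],
                             "gmi": gmi, "prior_discordance": prior_d,
                             "last_hba1c": last, "hba1c": y})

    def test_deterministic_under_seed(self):
        rows = self.linear_rows(300)
        assert fit_gam_lite(rows, seed=5) == fit_gam_lite(rows, seed=5)

    def test_no_gain_on_linear_truth(self):
        rows = self.linear_rows(800)
        gam = fit_gam_lite(rows, seed=1)
        lin = cross_validate_estimator(rows, GmiAdjuster(), 5, seed=1)
        assert gam.r2 <= lin.r2 + 0.02

    def test_gain_on_sinusoidal_truth(self):
        rng = np.random.default_rng(8)
        n = 1000
        x = rng.uniform(-3, 3, n)
        y = np.sin(2.0 * x) + rng.normal(0, 0.2, n)
        rows = pd.DataFrame({"subject_id": [f"S{i // 2}" for i in range(n)],
                             "gmi": x, "prior_discordance": rng.normal(size=n) * 0.01,
                             "last_hba1c": rng.normal(size=n) * 0.01, "hba1c": y})
        gam = fit_gam_lite(rows, seed=2)
        lin = cross_validate_estimator(rows, GmiAdjuster(), 5, seed=2)
        assert gam.r2 >= lin.r2 + 0.2

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_gam_lite(self.linear_rows(30), seed=0)
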