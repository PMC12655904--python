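"""OLS fitting, metrics, cross-validation and the published equations."""

import numpy as np
import pandas as pd
import pytest

from pfaser.qspr import (
    LinearModel,
    PUBLISHED_MODEL_NAMES,
    cross_validate_q2,
    denormalize_coefficients,
    evaluate,
    fit_ols,
    load_published_model,
    normalize_coefficients,
    predict,
)

from conftest import random_table


class TestFitOls:
    def test_noiseless_linear_truth_recovered(self):
        table = random_table(60, 5, seed=20)
        b = np.array([1.5, -2.0, 0.3, 0.0, 4.0])
        y = 2.5 + table.to_numpy() @ b
        model = fit_ols(table, y)
        assert np.allclose(model.coefficients, b, atol=1e-8)
        assert model.intercept == pytest.approx(2.5, abs=1e-8)
        assert model.metrics.r2 == pytest.approx(1.0, abs=1e-12)

    def test_single_predictor_closed_form(self):
        table = random_table(100, 1, seed=21)
        rng = np.random.default_rng(21)
        y = 3.0 + 0.7 * table.iloc[:, 0].to_numpy() + rng.normal(0, 0.5, 100)
        model = fit_ols(table, y)
        x = table.iloc[:, 0].to_numpy()
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert model.coefficients[0] == pytest.approx(slope, rel=1e-10)

    def test_constant_target_convention(self):
        table = random_table(30, 3, seed=22)
        model = fit_ols(table, np.full(30, 6.5))
        assert np.allclose(model.coefficients, 0.0, atol=1e-10)
        assert model.intercept == pytest.approx(6.5, abs=1e-10)
        assert model.metrics.r2 == 0.0  # stated convention, never 1

    def test_residuals_orthogonal_to_design(self):
        table = random_table(80, 6, seed=23)
        y = np.random.default_rng(23).standard_normal(80)
        model = fit_ols(table, y)
        resid = y - predict(model, table).to_numpy()
        assert abs(resid.sum()) < 1e-8
        assert np.all(np.abs(table.to_numpy().T @ resid) < 1e-8)

    def test_matches_normal_equations_oracle(self):
        """OLS solution equals the explicit (X'X)^-1 X'y oracle on random
        instances up to 12 predictors and 200 rows."""
        for seed, (n, m) in enumerate([(30, 2), (100, 8), (200, 12)]):
            table = random_table(n, m, seed=200 + seed, corr=0.3)
            y = np.random.default_rng(300 + seed).standard_normal(n)
            model = fit_ols(table, y)
            A = np.column_stack([np.ones(n), table.to_numpy()])
            beta = np.linalg.solve(A.T @ A, A.T @ y)
            assert np.allclose(
                np.concatenate([[model.intercept], model.coefficients]),
                beta,
                rtol=1e-8,
                atol=1e-10,
            )

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        table = random_table(120, 7, seed=24)
        y = np.random.default_rng(24).standard_normal(120)
        model = fit_ols(table, y)
        ref = sm.OLS(y, sm.add_constant(table.to_numpy())).fit()
        assert np.allclose(model.coefficients, ref.params[1:], rtol=1e-8)
        assert np.allclose(model.coef_standard_errors, ref.bse[1:], rtol=1e-6)
        assert model.metrics.r2 == pytest.approx(ref.rsquared, rel=1e-10)

    def test_rank_deficient_design_reported(self):
        table = random_table(50, 3, seed=25)
        table["dupe"] = table.iloc[:, 0]
        with pytest.raises(np.linalg.LinAlgError, match="dependent"):
            fit_ols(table, np.arange(50.0))

    def test_too_few_rows_rejected(self):
        table = random_table(5, 5, seed=26)
        with pytest.raises(ValueError):
            fit_ols(table, np.arange(5.0))


class TestEvaluateAndQ2:
    def test_perfect_and_null_predictions(self):
        table = random_table(40, 3, seed=27)
        y = 1.0 + table.iloc[:, 0].to_numpy()
        model = fit_ols(table, y)
        m = evaluate(model, table, y)
        assert (m.r2, m.rmse, m.mae) == pytest.approx((1.0, 0.0, 0.0), abs=1e-8)
        null = LinearModel(list(table.columns), np.zeros(3), float(y.mean()))
        assert evaluate(null, table, y).r2 == pytest.approx(0.0, abs=1e-12)

    def test_metrics_match_brute_force_sums(self):
        table = random_table(35, 4, seed=28)
        y = np.random.default_rng(28).standard_normal(35)
        model = fit_ols(table, y)
        m = evaluate(model, table, y)
        resid = y - predict(model, table).to_numpy()
        assert m.rmse == pytest.approx(np.sqrt((resid**2).mean()), abs=1e-10)
        assert m.mae == pytest.approx(np.abs(resid).mean(), abs=1e-10)
        assert m.mae <= m.rmse

    def test_zero_variance_target_undefined_r2(self):
        table = random_table(20, 2, seed=29)
        model = fit_ols(table, np.arange(20.0))
        assert np.isnan(evaluate(model, table, np.full(20, 3.0)).r2)

    def test_q2_noiseless_is_one(self):
        table = random_table(50, 4, seed=30)
        y = 1.0 + table.to_numpy() @ np.array([1.0, 2.0, -1.0, 0.5])
        assert cross_validate_q2(table, y) == pytest.approx(1.0, abs=1e-8)

    def test_press_shortcut_equals_refit_loo(self):
        """The leverage-based PRESS shortcut and explicit n-fold refitting
        are the same algebraic quantity."""
        table = random_table(30, 4, seed=31)
        y = np.random.default_rng(31).standard_normal(30) + table.iloc[:, 0].to_numpy()
        q2_press = cross_validate_q2(table, y, method="press")
        q2_refit = cross_validate_q2(table, y, method="refit")
        assert q2_press == pytest.approx(q2_refit, abs=1e-8)

    def test_pure_noise_q2_is_poor(self):
        table = random_table(150, 10, seed=32)
        y = np.random.default_rng(32).standard_normal(150)
        assert cross_validate_q2(table, y) < 0.2  # typically <= 0


class TestNormalization:
    def test_reference_mass_ratio(self):
        """raw 0.2222 with SD 221.65 gives the published normalized 49.25
        (consistency of the normalized = raw * SD convention)."""
        model = LinearModel(["Average Mass"], [0.2222], 8.03)
        out = normalize_coefficients(model, [221.653])
        assert out.normalized_coefficients[0] == pytest.approx(49.25, abs=0.01)

    def test_unit_sd_is_identity_and_roundtrip(self):
        model = LinearModel(list("abc"), [0.5, -1.0, 2.0], 1.0)
        out = normalize_coefficients(model, [1.0, 1.0, 1.0])
        assert np.allclose(out.normalized_coefficients, model.coefficients)
        out2 = normalize_coefficients(model, [2.0, 3.0, 0.5])
        assert np.allclose(denormalize_coefficients(out2), model.coefficients, atol=1e-12)

    def test_nonpositive_sd_rejected(self):
        model = LinearModel(["a"], [1.0], 0.0)
        with pytest.raises(ValueError):
            normalize_coefficients(model, [0.0])


class TestPublishedModels:
    def test_all_four_models_have_eleven_coefficients(self):
        for name in PUBLISHED_MODEL_NAMES:
            model = load_published_model(name)
            assert len(model.coefficients) == 11
            assert len(model.descriptor_names) == 11

    @pytest.mark.parametrize(
        "name, intercept",
        [
            ("TB-ERalpha", 8.03),
            ("TB-ERbeta", 8.02),
            ("CE-ERalpha", 5.95),
            ("CE-ERbeta", 6.02),
        ],
    )
    def test_zero_descriptor_vector_returns_intercept(self, name, intercept):
        model = load_published_model(name)
        zero = pd.DataFrame(
            np.zeros((1, 11)), columns=model.descriptor_names, index=["z"]
        )
        assert predict(model, zero)["z"] == pytest.approx(intercept, abs=1e-12)

    def test_reference_coefficients(self):
        tb_a = load_published_model("TB-ERalpha")
        coef = dict(zip(tb_a.descriptor_names, tb_a.coefficients))
        assert coef["Number of Freely Rotating Bonds"] == pytest.approx(-0.3843)
        assert coef["Average Mass"] == pytest.approx(0.2222)
        ce_b = load_published_model("CE-ERbeta")
        coef_b = dict(zip(ce_b.descriptor_names, ce_b.coefficients))
        assert coef_b["Density"] == pytest.approx(0.3057)

    def test_alias_spellings(self):
        assert load_published_model("tb-era").name == "TB-ERalpha"
        assert load_published_model("CE-ERb").name == "CE-ERbeta"
        with pytest.raises(KeyError):
            load_published_model("nonsense")

    def test_json_roundtrip(self):
        model = load_published_model("TB-ERbeta")
        back = LinearModel.from_json(model.to_json())
        assert back.descriptor_names == model.descriptor_names
        assert np.allclose(back.coefficients, model.coefficients)
        assert back.intercept == model.intercept


def test_confidence_interval_coverage():
    """95% coefficient CIs cover the truth at the nominal rate (within 5
    percentage points) across 200 seeded replicates."""
    from scipy import stats

    n, m = 200, 12
    b_true = np.linspace(-1.0, 1.0, m)
    covered = 0
    total = 0
    for seed in range(200):
        table = random_table(n, m, seed=1000 + seed, corr=0.2)
        rng = np.random.default_rng(5000 + seed)
        y = 0.5 + table.to_numpy() @ b_true + rng.normal(0, 0.4, n)
        model = fit_ols(table, y)
        tcrit = stats.t.ppf(0.975, n - m - 1)
        half = tcrit * model.coef_standard_errors
        covered += int(
            np.sum(np.abs(model.coefficients - b_true) <= half)
        )
        total += m
    rate = covered / total
    assert 0.90 <= rate <= 1.0
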