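"""Design building, OLS, LOO-CV, backward selection, AICc and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from phenomatch import (
    ModelSpec,
    Term,
    TruthParams,
    aicc,
    backward_select,
    build_design,
    fit_model,
    gen_recruitment,
    loo_cv_rmse,
    ols_fit,
    preset_specs,
    residual_diagnostics,
    sample_predictors,
)
from phenomatch.modeling import FitResult


def simple_spec(*names, response="y"):
    return ModelSpec(response=response, terms=tuple(Term(n) for n in names))


class TestBuildDesign:
    def test_centred_columns_have_zero_mean(self, recruitment_records):
        X, _, _ = build_design(recruitment_records(60), preset_specs()["recruitment"])
        for col in ("PM", "CA", "WT"):
            assert abs(X[col].mean()) < 1e-10

    def test_dummy_split_at_median(self):
        rec = pd.DataFrame({"CA": [10.0, 20, 30, 40], "x": [1.0, 2, 3, 5],
                            "y": [1.0, 2, 3, 4]})
        spec = ModelSpec(response="y", dummy_var="CA",
                         terms=(Term("x", 1, by_dummy=True),))
        X, _, _ = build_design(rec, spec)
        # median CA = 25: first two years are low, last two high
        assert list(X["x:D_low"] != 0) == [True, True, False, False]
        assert list(X["x:D_high"] != 0) == [False, False, True, True]

    def test_interaction_columns_are_disjoint(self, recruitment_records):
        X, _, _ = build_design(recruitment_records(40), preset_specs()["recruitment"])
        assert np.all(X["LS:D_low"] * X["LS:D_high"] == 0)
        assert np.all(X["PM^2:D_low"] * X["PM^2:D_high"] == 0)

    def test_missing_field_is_named(self, recruitment_records):
        rec = recruitment_records(20).drop(columns="WT")
        with pytest.raises(KeyError, match="WT"):
            build_design(rec, preset_specs()["recruitment"])

    def test_constant_predictor_rejected(self):
        rec = pd.DataFrame({"x": [1.0] * 8, "y": np.arange(8.0)})
        with pytest.raises(ValueError, match="constant"):
            build_design(rec, simple_spec("x"))


class TestOlsFit:
    def test_exact_line_through_points(self):
        fit = ols_fit(np.column_stack([np.ones(3), [0.0, 1, 2]]), [1.0, 3, 5])
        assert fit.params.to_numpy() == pytest.approx([1.0, 2.0])
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.residuals == pytest.approx(np.zeros(3), abs=1e-12)

    def test_leverages_are_valid(self, recruitment_records):
        fit = fit_model(recruitment_records(80), preset_specs()["recruitment"])
        assert np.all((fit.leverage >= 0) & (fit.leverage <= 1))
        assert fit.leverage.sum() == pytest.approx(fit.k)

    def test_collinear_columns_are_named(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"const": 1.0, "a": x, "b": 2 * x})
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            ols_fit(X, np.arange(10.0))

    def test_interaction_contrast_matches_generative_ordering(self, recruitment_records):
        # truth has a much stronger hatching-duration effect at low density
        fit = fit_model(recruitment_records(300), preset_specs()["recruitment"])
        assert fit.params["LS:D_low"] > fit.params["LS:D_high"]


class TestLooCv:
    def test_noiseless_linear_data_has_zero_error(self):
        rng = np.random.default_rng(1)
        rec = pd.DataFrame({"x": rng.normal(0, 1, 20)})
        rec["y"] = 2.0 + 3.0 * rec["x"]
        assert loo_cv_rmse(rec, simple_spec("x")) == pytest.approx(0.0, abs=1e-10)

    def test_three_point_hand_computation(self):
        # leave-out errors are (2, -1, 2): RMSE = sqrt(3)
        rec = pd.DataFrame({"x": [0.0, 1, 2], "y": [0.0, 1, 0]})
        assert loo_cv_rmse(rec, simple_spec("x")) == pytest.approx(np.sqrt(3))

    def test_press_identity_with_fixed_design(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(12, 30))
            rec = pd.DataFrame({"a": rng.normal(0, 1, n), "b": rng.normal(0, 1, n)})
            rec["y"] = rng.normal(0, 1, n)
            spec = ModelSpec(response="y", terms=(Term("a"), Term("b"), Term("a", 2)))
            X, y, _ = build_design(rec, spec)
            fit = ols_fit(X, y)
            press = np.sqrt(np.mean((fit.residuals / (1 - fit.leverage)) ** 2))
            cv = loo_cv_rmse(rec, spec, refit_centring=False)
            assert cv == pytest.approx(press, abs=1e-10)


class TestBackwardSelect:
    def test_trace_is_non_increasing(self, recruitment_records):
        trace = backward_select(recruitment_records(60), preset_specs("candidate")["recruitment"])
        cvs = [s.cv_rmse for s in trace.steps]
        assert all(b <= a for a, b in zip(cvs, cvs[1:]))

    def test_pure_noise_selects_intercept_only_in_majority(self):
        wins = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            rec = pd.DataFrame({"x0": rng.normal(0, 1, 40), "x1": rng.normal(0, 1, 40)})
            rec["y"] = rng.normal(0, 1, 40)
            trace = backward_select(rec, simple_spec("x0", "x1"))
            wins += len(trace.final_spec.terms) == 0
        assert wins > n_seeds / 2

    def test_marginality_keeps_main_effect_under_quadratic(self):
        rng = np.random.default_rng(2)
        rec = pd.DataFrame({"x": rng.normal(0, 1, 60)})
        rec["y"] = 1.0 + 0.0 * rec["x"] + 2.0 * (rec["x"] - rec["x"].mean()) ** 2
        rec["y"] += rng.normal(0, 0.05, 60)
        spec = ModelSpec(response="y", terms=(Term("x", 1), Term("x", 2)))
        trace = backward_select(rec, spec)
        labels = [t.labels()[0] for t in trace.final_spec.terms]
        # x^2 carries all the signal and pins the main effect in place
        assert "x^2" in labels and "x" in labels

    def test_interaction_collapses_before_main_effect_drops(self):
        rng = np.random.default_rng(3)
        n = 80
        rec = pd.DataFrame({"g": rng.lognormal(0, 1, n), "x": rng.normal(0, 1, n)})
        rec["y"] = 0.9 * (rec["x"] - rec["x"].mean()) + rng.normal(0, 0.1, n)
        spec = ModelSpec(response="y", dummy_var="g",
                         terms=(Term("x", 1, by_dummy=True),))
        trace = backward_select(rec, spec)
        # the same slope in both halves: the interaction collapses to a main effect
        final = trace.final_spec.terms
        assert final == (Term("x", 1, by_dummy=False),)
        assert any(s.dropped and "interaction" in s.dropped for s in trace.steps)


class TestAicc:
    def test_direct_formula_evaluation(self):
        assert aicc(n=10, rss=2.5, k=3) == pytest.approx(
            10 * np.log(0.25) + 6 + 4, abs=1e-9
        )
        assert aicc(n=10, rss=2.5, k=3) == pytest.approx(-3.863, abs=0.001)

    def test_undefined_for_tiny_samples(self):
        with pytest.raises(ValueError, match="n > k"):
            aicc(n=4, rss=1.0, k=3)

    def test_aicc_best_matches_cv_selection_when_signal_is_strong(self):
        from phenomatch import aicc_from_fit, fit_model

        rng = np.random.default_rng(8)
        n = 150
        rec = pd.DataFrame({f"x{i}": rng.normal(0, 1, n) for i in range(4)})
        rec["y"] = 1.0 + 1.5 * rec["x0"] + rng.normal(0, 0.1, n)
        trace = backward_select(rec, simple_spec("x0", "x1", "x2", "x3"))
        aiccs = [(aicc_from_fit(fit_model(rec, s.spec)), i)
                 for i, s in enumerate(trace.steps)]
        best_step = min(aiccs)[1]
        assert trace.steps[best_step].spec == trace.final_spec


class TestDiagnostics:
    def make_fit(self, residuals, fitted=None):
        residuals = np.asarray(residuals, float)
        n = len(residuals)
        fitted = np.zeros(n) if fitted is None else np.asarray(fitted, float)
        one = pd.Series([0.0], index=["const"])
        return FitResult(params=one, bse=one, pvalues=one, r_squared=0.0,
                         rss=float(residuals @ residuals), residuals=residuals,
                         fitted=fitted, leverage=np.full(n, 1.0 / n), n=n, k=1)

    def test_perfect_alternation_has_autocorr_minus_one(self):
        e = np.tile([1.0, -1.0], 50)
        rep = residual_diagnostics(self.make_fit(e, fitted=np.arange(100.0)))
        assert rep.lag1_autocorr == pytest.approx(-1.0, abs=0.02)
        assert not rep.autocorr_ok

    def test_iid_gaussian_residuals_pass_at_nominal_rate(self):
        passes = np.zeros(3)
        n_seeds = 60
        for seed in range(n_seeds):
            rng = np.random.default_rng(500 + seed)
            rep = residual_diagnostics(
                self.make_fit(rng.normal(0, 1, 1000), fitted=rng.normal(0, 1, 1000))
            )
            passes += [rep.autocorr_ok, rep.homogeneity_ok, rep.normality_ok]
        assert np.all(passes / n_seeds >= 0.85)

    def test_strong_ar1_residuals_fail_autocorrelation(self):
        rng = np.random.default_rng(6)
        e = np.zeros(200)
        for t in range(1, 200):
            e[t] = 0.8 * e[t - 1] + rng.normal()
        rep = residual_diagnostics(self.make_fit(e, fitted=rng.normal(0, 1, 200)))
        assert not rep.autocorr_ok

    def test_degenerate_residuals_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            residual_diagnostics(self.make_fit(np.zeros(20)))


class TestPresets:
    def test_recruitment_spec_coefficient_slots(self):
        spec = preset_specs()["recruitment"]
        assert spec.column_names() == [
            "const", "LS:D_low", "LS:D_high", "PM", "PM^2:D_low", "PM^2:D_high",
            "S^2", "CA", "WT",
        ]
        assert spec.n_coefficients == 9

    def test_disease_temperature_interaction_only_a_candidate(self):
        selected = preset_specs()["peak_spawning"]
        candidate = preset_specs("candidate")["peak_spawning"]
        assert not any(t.by_dummy for t in selected.terms)
        assert any(t.by_dummy and t.predictor == "ST" for t in candidate.terms)

    def test_all_presets_build_valid_designs(self, recruitment_records):
        rng = np.random.default_rng(4)
        rec = recruitment_records(50)
        rec["PS"] = rng.normal(135, 5, 50)
        rec["ST"] = rng.normal(8, 1.5, 50)
        rec["MT"] = rng.normal(11, 1.5, 50)
        rec["MS"] = rng.normal(180, 15, 50)
        rec["P"] = (rec.index >= rec.index[25]).astype(float)
        for stage in ("selected", "candidate"):
            for spec in preset_specs(stage).values():
                X, y, _ = build_design(rec, spec)
                assert np.linalg.matrix_rank(X.to_numpy()) == X.shape[1]
                assert len(y) == 50


def test_recovery_of_generative_coefficients_single_replicate(recruitment_records):
    """With zero noise the reference coefficients are recovered exactly."""
    rec = recruitment_records(120, seed=3, sigma=0.0)
    fit = fit_model(rec, preset_specs()["recruitment"])
    truth = TruthParams.windermere()
    expected = {
        "const": truth.b0, "LS:D_low": truth.b1_low, "LS:D_high": truth.b1_high,
        "PM": truth.b2, "PM^2:D_low": truth.b3_low, "PM^2:D_high": truth.b3_high,
        "S^2": truth.b4, "CA": truth.b5, "WT": truth.b6,
    }
    for name, val in expected.items():
        assert fit.params[name] == pytest.approx(val, rel=1e-6, abs=1e-13)
    assert fit.r_squared == pytest.approx(1.0)
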