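"""Cox model families: oracle equivalence, selection behavior, penalized
limits, prediction identities."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from gistnomo._coxlib import breslow_gradient, breslow_loglik
from gistnomo.models import (
    cox_with_lasso,
    fit_cox,
    fit_penalized_cox,
    predict_risk,
    predict_survival,
    two_stage_select_and_fit,
)
from gistnomo.prep import EncodedCohort, encode_dummies
from gistnomo.synthetic import generate_raw_cohort

from conftest import signal_config


def tiny_encoded(x, time, event) -> EncodedCohort:
    features = pd.DataFrame({f"x{i}": x[:, i] for i in range(x.shape[1])})
    return EncodedCohort(features=features,
                         time=pd.Series(time, dtype=float),
                         os_event=pd.Series(event, dtype=int),
                         css_event=pd.Series(event, dtype=int),
                         mode="reference", references={}, levels={})


class TestFitCox:
    def test_symmetric_groups_give_zero_coefficient(self):
        x = np.array([[0.0], [1.0], [0.0], [1.0]])
        enc = tiny_encoded(x, [1, 1, 2, 2], [1, 1, 1, 1])
        fit = fit_cox(enc, "os")
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-8)

    def test_grid_search_oracle_on_hand_data(self, hand_survival):
        """The fitted coefficient maximizes the explicit Breslow partial
        likelihood, checked against a dense grid search."""
        x, time, event = hand_survival

        def naive_pl(b):
            eta = (x @ np.atleast_1d(b)).ravel()
            ll = 0.0
            for t in np.unique(time[event == 1]):
                d = (time == t) & (event == 1)
                risk = time >= t
                ll += eta[d].sum() - d.sum() * np.log(np.exp(eta[risk]).sum())
            return ll

        grid = np.linspace(-3, 3, 6001)
        best = grid[np.argmax([naive_pl(b) for b in grid])]
        fit = fit_cox(tiny_encoded(x, time, event), "os")
        assert fit.beta[0] == pytest.approx(best, abs=1e-3)

    def test_score_equation_satisfied(self, encoded_ref):
        fit = fit_cox(encoded_ref, "os")
        g = breslow_gradient(fit.beta, encoded_ref.features.to_numpy(),
                             encoded_ref.time.to_numpy(),
                             encoded_ref.os_event.to_numpy())
        assert np.max(np.abs(g)) < 1e-6

    def test_matches_statsmodels(self, encoded_ref):
        from statsmodels.duration.hazard_regression import PHReg

        fit = fit_cox(encoded_ref, "os")
        sm_fit = PHReg(encoded_ref.time.to_numpy(),
                       encoded_ref.features.to_numpy(),
                       status=encoded_ref.os_event.to_numpy(),
                       ties="breslow").fit(disp=False)
        assert np.allclose(fit.beta, sm_fit.params, atol=1e-4)

    def test_hr_equals_exp_beta(self, encoded_ref):
        fit = fit_cox(encoded_ref, "os")
        assert np.allclose(fit.hr_ci_p["HR"].to_numpy(),
                           np.exp(fit.beta), atol=1e-12)

    def test_time_shift_invariance(self, hand_survival):
        x, time, event = hand_survival
        a = fit_cox(tiny_encoded(x, time, event), "os")
        b = fit_cox(tiny_encoded(x, time + 100.0, event), "os")
        assert a.beta[0] == pytest.approx(b.beta[0], abs=1e-8)

    def test_feature_scaling_scales_beta(self, hand_survival):
        x, time, event = hand_survival
        a = fit_cox(tiny_encoded(x, time, event), "os")
        b = fit_cox(tiny_encoded(10.0 * x, time, event), "os")
        assert b.beta[0] == pytest.approx(a.beta[0] / 10.0, abs=1e-6)

    def test_no_events_is_error(self):
        enc = tiny_encoded(np.ones((3, 1)), [1, 2, 3], [0, 0, 0])
        with pytest.raises(ValueError, match="event"):
            fit_cox(enc, "os")


class TestTwoStage:
    def test_alpha_one_keeps_everything(self, encoded_ref):
        full = fit_cox(encoded_ref, "os")
        ts = two_stage_select_and_fit(encoded_ref, "os", alpha=1.0)
        assert set(ts.feature_names) == set(full.feature_names)
        assert np.allclose(np.sort(ts.beta), np.sort(full.beta), atol=1e-8)

    def test_nesting_of_selection_stages(self, encoded_ref):
        ts = two_stage_select_and_fit(encoded_ref, "os")
        trace = ts.selection_trace
        assert set(ts.feature_names) <= set(trace["advanced"])
        assert set(trace["advanced"]) <= set(trace["univariate_p"])

    def test_strong_signal_kept_noise_dropped(self):
        cohort = generate_raw_cohort(signal_config(n=3000, seed=42))
        enc = encode_dummies(cohort, mode="reference")
        ts = two_stage_select_and_fit(enc, "os")
        assert "Sex_Male" in ts.feature_names
        assert "Tumor_size_>=10 cm" in ts.feature_names
        # Chemotherapy has a zero true effect in this generator
        assert "Chemotherapy_Yes" not in ts.feature_names

    def test_full_mode_rejected(self, encoded_full):
        with pytest.raises(ValueError, match="reference"):
            two_stage_select_and_fit(encoded_full, "os")


class TestPenalized:
    def test_large_lambda_zeroes_lasso_and_enet(self, encoded_full):
        for penalty in ("lasso", "enet"):
            fit, path = fit_penalized_cox(encoded_full, "os", penalty,
                                          seed=0, alphas=[50.0, 1e-3])
            assert np.allclose(path.coef_path[0], 0.0)

    def test_tiny_lambda_matches_unpenalized(self, encoded_ref):
        f0 = fit_cox(encoded_ref, "os")
        fit, path = fit_penalized_cox(encoded_ref, "os", "lasso", seed=0,
                                      alphas=[1e-8], tol=1e-12)
        assert np.max(np.abs(path.coef_path[0] - f0.beta)) < 1e-4

    def test_ridge_never_thresholds(self, encoded_full):
        fit, path = fit_penalized_cox(encoded_full, "os", "ridge", seed=0,
                                      alphas=np.geomspace(1.0, 1e-4, 8))
        assert np.all(path.coef_path != 0.0)
        assert path.n_nonzero == encoded_full.features.shape[1]

    def test_cv_choice_deterministic_given_seed(self, encoded_full):
        a = fit_penalized_cox(encoded_full, "os", "lasso", seed=3,
                              n_alphas=25)[1]
        b = fit_penalized_cox(encoded_full, "os", "lasso", seed=3,
                              n_alphas=25)[1]
        assert a.chosen_alpha == b.chosen_alpha
        assert np.array_equal(a.cv_deviance, b.cv_deviance)

    def test_unknown_penalty_rejected(self, encoded_full):
        with pytest.raises(ValueError):
            fit_penalized_cox(encoded_full, "os", "scad")


class TestCoxWithLasso:
    def test_feature_set_equals_lasso_nonzeros(self, encoded_full):
        lasso_fit, _ = fit_penalized_cox(encoded_full, "os", "lasso",
                                         seed=1, n_alphas=30)
        refit = cox_with_lasso(encoded_full, "os", lasso_fit)
        expected = set(refit.selection_trace["basis"])
        assert set(refit.feature_names) == expected
        assert expected <= set(lasso_fit.nonzero_features)

    def test_single_dummy_selection_is_univariate_cox(self, encoded_full):
        lasso_fit, _ = fit_penalized_cox(encoded_full, "os", "lasso",
                                         seed=1, n_alphas=30)
        keep = lasso_fit.nonzero_features[0]
        lasso_fit.beta = np.where(
            np.array(lasso_fit.feature_names) == keep, lasso_fit.beta, 0.0)
        refit = cox_with_lasso(encoded_full, "os", lasso_fit)
        uni = fit_cox(encoded_full, "os", features=[keep])
        assert refit.feature_names == [keep]
        assert refit.beta[0] == pytest.approx(uni.beta[0], abs=1e-8)

    def test_empty_selection_is_error(self, encoded_full):
        lasso_fit, _ = fit_penalized_cox(encoded_full, "os", "lasso",
                                         seed=1, n_alphas=30)
        lasso_fit.beta = np.zeros_like(lasso_fit.beta)
        with pytest.raises(ValueError, match="nonzero"):
            cox_with_lasso(encoded_full, "os", lasso_fit)


class TestPrediction:
    def test_zero_lp_gives_baseline_survival(self, hand_survival):
        x, time, event = hand_survival
        fit = fit_cox(tiny_encoded(x, time, event), "os")
        row = pd.DataFrame({"x0": [0.0]})
        s = predict_survival(fit, row, 5.0)
        idx = np.searchsorted(fit.baseline_times, 5.0, side="right") - 1
        assert s[0] == pytest.approx(np.exp(-fit.baseline_cumhaz[idx]))

    def test_lp_linearity(self, hand_survival):
        x, time, event = hand_survival
        fit = fit_cox(tiny_encoded(x, time, event), "os")
        row = pd.DataFrame({"x0": [1.0]})
        lp1 = predict_risk(fit, row)[0]
        fit.beta = fit.beta * 2
        assert predict_risk(fit, row)[0] == pytest.approx(2 * lp1)

    def test_survival_matches_direct_breslow_recomputation(self):
        """S(t|x) from the stored baseline equals a from-scratch Breslow
        computation on a 10-subject dataset."""
        x = np.array([[1.0], [0.0], [1.0], [0.0], [1.0],
                      [0.0], [1.0], [0.0], [1.0], [0.0]])
        time = np.array([2.0, 3.0, 4.0, 4.0, 6.0, 8.0, 9.0, 12.0, 14.0, 15.0])
        event = np.array([1, 0, 1, 1, 0, 1, 1, 1, 0, 1])
        fit = fit_cox(tiny_encoded(x, time, event), "os")
        beta = fit.beta[0]
        t_eval = float(np.median(time))
        h0 = 0.0
        for t in np.unique(time[event == 1]):
            if t <= t_eval:
                d = int(((time == t) & (event == 1)).sum())
                h0 += d / np.exp(beta * x[time >= t, 0]).sum()
        expect = np.exp(-h0) ** np.exp(beta * 1.0)
        got = predict_survival(fit, pd.DataFrame({"x0": [1.0]}), t_eval)[0]
        assert got == pytest.approx(expect, rel=1e-10)

    def test_horizon_beyond_grid_warns(self, hand_survival):
        x, time, event = hand_survival
        fit = fit_cox(tiny_encoded(x, time, event), "os")
        with pytest.warns(UserWarning, match="beyond"):
            predict_survival(fit, pd.DataFrame({"x0": [0.0]}), 1e6)
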