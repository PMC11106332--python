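"""Time-dependent AUC estimator and the split-by-model comparison."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gistnomo.horizon import (
    HorizonReport,
    cumulative_dynamic_auc,
    run_experiment,
    summarize,
)
from gistnomo.models import fit_cox, two_stage_select_and_fit
from gistnomo.stats import generate_balanced_splits
from gistnomo.prep import encode_dummies
from gistnomo.synthetic import generate_raw_cohort

from conftest import signal_config


def brute_force_auc(scores, time, event, horizon):
    """Direct pairwise IPCW enumeration, written independently of the
    vectorized implementation."""
    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)

    def censor_km(x, before=False):
        g, at_risk = 1.0, len(time)
        out = 1.0
        for u in np.unique(time):
            d = int(((time == u) & (event == 0)).sum())
            g *= 1 - d / at_risk if at_risk > 0 else 1.0
            at_risk -= int((time == u).sum())
            if (u < x) if before else (u <= x):
                out = g
        return out

    num = den = 0.0
    for i in range(len(time)):
        if time[i] <= horizon and event[i] == 1:
            wi = 1.0 / censor_km(time[i], before=True)
            for j in range(len(time)):
                if time[j] > horizon:
                    wj = 1.0 / censor_km(horizon)
                    conc = (1.0 if scores[i] > scores[j]
                            else 0.5 if scores[i] == scores[j] else 0.0)
                    num += wi * wj * conc
                    den += wi * wj
    return num / den


class TestCumulativeDynamicAUC:
    def test_perfect_separation_no_censoring(self):
        time = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        event = np.ones(6, dtype=int)
        scores = np.array([5, 4, 3, 0, -1, -2], dtype=float)
        assert cumulative_dynamic_auc(scores, time, event, 5.0) == 1.0

    def test_constant_scores_give_half(self):
        time = np.array([1, 2, 8, 9], dtype=float)
        event = np.ones(4, dtype=int)
        assert cumulative_dynamic_auc(np.zeros(4), time, event,
                                      5.0) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_brute_force_on_censored_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        time = np.round(rng.exponential(10, n), 1) + 0.5
        event = rng.integers(0, 2, n)
        event[rng.integers(0, n)] = 1
        scores = rng.normal(size=n)
        h = float(np.median(time))
        if not ((time <= h) & (event == 1)).any() or not (time > h).any():
            pytest.skip("degenerate draw lacks cases or controls")
        ours = cumulative_dynamic_auc(scores, time, event, h)
        brute = brute_force_auc(scores, time, event, h)
        assert ours == pytest.approx(brute, abs=1e-12)

    def test_matches_scikit_survival(self, rng):
        from sksurv.metrics import cumulative_dynamic_auc as sk_auc
        from sksurv.util import Surv

        n = 250
        time = rng.exponential(20, n)
        event = rng.integers(0, 2, n)
        scores = rng.normal(size=n)
        y = Surv.from_arrays(event=event.astype(bool), time=time)
        ours = cumulative_dynamic_auc(scores, time, event, 10.0)
        theirs = float(sk_auc(y, y, scores, [10.0])[0][0])
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_reduces_to_binary_auc_without_early_censoring(self, rng):
        from sklearn.metrics import roc_auc_score

        n = 300
        time = rng.exponential(30, n) + 20.0  # nothing censored before h
        event = rng.integers(0, 2, n)
        scores = rng.normal(size=n) + (time < 40) * 0.5
        h = 19.0
        # no subject has time <= h ... shift some events below h
        time[:50] = rng.uniform(1, 15, 50)
        event[:50] = 1
        ours = cumulative_dynamic_auc(scores, time, event, h)
        labels = (time <= h) & (event == 1)
        assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-10)

    def test_monotone_transform_invariance(self, rng):
        n = 100
        time = rng.exponential(15, n)
        event = rng.integers(0, 2, n)
        scores = rng.normal(size=n)
        h = float(np.quantile(time, 0.4))
        a = cumulative_dynamic_auc(scores, time, event, h)
        b = cumulative_dynamic_auc(np.exp(2.0 * scores), time, event, h)
        assert a == pytest.approx(b, abs=1e-12)

    def test_no_cases_warns_and_returns_nan(self):
        time = np.array([10.0, 11.0, 12.0])
        event = np.array([1, 1, 1])
        with pytest.warns(UserWarning, match="undefined"):
            out = cumulative_dynamic_auc(np.zeros(3), time, event, 5.0)
        assert np.isnan(out)


@pytest.fixture(scope="module")
def small_experiment():
    cohort = generate_raw_cohort(signal_config(n=900, seed=31))
    enc = encode_dummies(cohort, mode="reference")
    splits = generate_balanced_splits(cohort, n_splits=4, seed=32)
    return cohort, enc, splits


class TestRunExperiment:
    def test_single_model_tops_every_split(self, small_experiment):
        _, enc, splits = small_experiment
        specs = {"only": lambda er, ef, oc, si: fit_cox(er, oc)}
        rep = run_experiment(enc, splits, specs, horizons=(12.0, 60.0))
        summ = summarize(rep)
        assert (summ["top1"] == "4/4").all()
        assert (summ["top3"] == "4/4").all()

    def test_monotone_transform_gives_identical_aucs(self, small_experiment):
        _, enc, splits = small_experiment

        def base(er, ef, oc, si):
            return fit_cox(er, oc)

        def doubled(er, ef, oc, si):
            f = fit_cox(er, oc)
            f.beta = 2.0 * f.beta  # strictly monotone transform of scores
            return f

        rep = run_experiment(enc, splits, {"a": base, "b": doubled},
                             horizons=(60.0,))
        g = rep.grid.pivot(index="split", columns="model", values="auc")
        assert np.allclose(g["a"], g["b"], atol=1e-12)

    def test_true_model_beats_noise_model(self, small_experiment):
        _, enc, splits = small_experiment
        rng = np.random.default_rng(0)

        def true_model(er, ef, oc, si):
            return fit_cox(er, oc, features=["age_years", "Sex_Male",
                                             "Tumor_size_>=10 cm",
                                             "AJCC_stage_IV"])

        def noise_model(er, ef, oc, si):
            f = fit_cox(er, oc, features=["age_years", "Sex_Male"])
            f.beta = rng.normal(size=2)  # scores unrelated to outcome
            return f

        rep = run_experiment(enc, splits, {"true": true_model,
                                           "noise": noise_model},
                             horizons=(60.0,))
        summ = summarize(rep).set_index("model")
        top1_true = int(summ.loc["true", "top1"].split("/")[0])
        assert top1_true >= 3

    def test_failed_model_excluded_from_ranking(self, small_experiment):
        _, enc, splits = small_experiment

        def ok(er, ef, oc, si):
            return fit_cox(er, oc, features=["age_years"])

        def broken(er, ef, oc, si):
            raise RuntimeError("synthetic failure")

        rep = run_experiment(enc, splits, {"ok": ok, "broken": broken},
                             horizons=(60.0,))
        assert rep.grid[rep.grid.model == "broken"]["auc"].isna().all()
        summ = summarize(rep).set_index("model")
        assert summ.loc["ok", "top1"] == "4/4"


class TestSummarize:
    def test_mean_and_quartiles(self):
        grid = pd.DataFrame({
            "model": ["m"] * 3, "split": [0, 1, 2],
            "horizon": [6.0] * 3, "auc": [0.7, 0.8, 0.9],
        })
        rep = HorizonReport(grid=grid, horizons=(6.0,), n_splits=3,
                            models=["m"])
        row = summarize(rep).iloc[0]
        assert row["mean_auc"] == pytest.approx(0.8)
        assert row["q25"] == pytest.approx(0.75)
        assert row["q75"] == pytest.approx(0.85)

    def test_top_counts_match_exhaustive_ranking(self, rng):
        models = ["a", "b", "c"]
        rows = []
        aucs = {}
        for s in range(4):
            for m in models:
                v = float(rng.uniform(0.5, 0.9))
                aucs[(m, s)] = v
                rows.append((m, s, 6.0, v))
        grid = pd.DataFrame(rows, columns=["model", "split", "horizon", "auc"])
        rep = HorizonReport(grid=grid, horizons=(6.0,), n_splits=4,
                            models=models)
        summ = summarize(rep).set_index("model")
        for m in models:
            exp_top1 = sum(
                1 for s in range(4)
                if aucs[(m, s)] == max(aucs[(mm, s)] for mm in models))
            assert summ.loc[m, "top1"] == f"{exp_top1}/4"

    def test_topk_conservation_without_ties(self, small_experiment):
        _, enc, splits = small_experiment

        def mk(feats):
            return lambda er, ef, oc, si: fit_cox(er, oc, features=feats)

        specs = {"m1": mk(["age_years"]), "m2": mk(["age_years", "Sex_Male"]),
                 "m3": mk(["age_years", "Tumor_size_>=10 cm"])}
        rep = run_experiment(enc, splits, specs, horizons=(60.0,))
        summ = summarize(rep)
        tops1 = sum(int(s.split("/")[0]) for s in summ["top1"])
        tops3 = sum(int(s.split("/")[0]) for s in summ["top3"])
        assert tops1 == 4
        assert tops3 == 3 * 4
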