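"""Compare the five nomogram models by time-dependent AUC across splits.

For each outcome, every model is re-fit on each accepted split's train
cohort (selection and cross-validation included) and scored on the test
cohort at six horizons.  Writes the long-format AUC grid and the summary
table (mean AUC, interquartile range, top-1/top-3 counts per horizon).
"""

import argparse
import json
from pathlib import Path

import numpy as np

from gistnomo.horizon import run_experiment, summarize
from gistnomo.models import (cox_with_lasso, fit_penalized_cox,
                             two_stage_select_and_fit)
from gistnomo.prep import encode_dummies
from gistnomo.stats import SplitSet, balance_tests
from gistnomo.synthetic import read_cohort


def make_fitter(name, seed):
    def fitter(enc_ref, enc_full, outcome, split_idx):
        if name == "two_stage":
            return two_stage_select_and_fit(enc_ref, outcome)
        if name in ("lasso", "ridge", "enet"):
            return fit_penalized_cox(enc_full, outcome, name,
                                     seed=seed + split_idx)[0]
        lf, _ = fit_penalized_cox(enc_full, outcome, "lasso",
                                  seed=seed + split_idx)
        return cox_with_lasso(enc_full, outcome, lf)
    return fitter


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=5)
    ap.add_argument("--dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = read_cohort(args.dir / "cohort_completed.csv")
    raw = json.loads((args.dir / "splits.json").read_text())
    splits = SplitSet(
        splits=[(np.array(s["train"]), np.array(s["test"]),
                 balance_tests(cohort.iloc[s["train"]],
                               cohort.iloc[s["test"]]))
                for s in raw["splits"]],
        ratio=raw["ratio"], alpha=raw["alpha"], n_attempts=raw["n_attempts"])

    enc = encode_dummies(cohort, mode="reference")
    enc_full = encode_dummies(cohort, mode="full")
    specs = {m: make_fitter(m, args.seed)
             for m in ("two_stage", "lasso", "ridge", "enet", "cox_lasso")}

    for outcome in ("os", "css"):
        report = run_experiment(enc, splits, specs, outcome=outcome,
                                encoded_full=enc_full)
        report.grid.to_csv(args.dir / f"auc_grid_{outcome}.csv", index=False)
        summ = summarize(report)
        summ.to_csv(args.dir / f"auc_summary_{outcome}.csv", index=False)
        print(f"\n=== {outcome.upper()} ===")
        print(summ.round(3).to_string(index=False))
        winners = (summ.sort_values("mean_auc", ascending=False)
                   .groupby("horizon_months").head(1))
        best = winners["model"].value_counts().idxmax()
        print(f"most often best by mean AUC: {best}")


if __name__ == "__main__":
    main()
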