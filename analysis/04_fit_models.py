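"""Construct the five Cox nomogram models on the first accepted split.

For each outcome (OS, CSS): the two-stage selected Cox model with its
hazard-ratio table, the three penalized fits with their cross-validated
lambdas and nonzero-feature counts, and the lasso-selected refit.  Writes
one JSON per (model, outcome) plus a combined hazard-ratio table.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from gistnomo.models import (cox_with_lasso, fit_penalized_cox,
                             two_stage_select_and_fit)
from gistnomo.prep import encode_dummies
from gistnomo.synthetic import read_cohort


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=4)
    ap.add_argument("--dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = read_cohort(args.dir / "cohort_completed.csv")
    splits = json.loads((args.dir / "splits.json").read_text())
    train = cohort.iloc[splits["splits"][0]["train"]].reset_index(drop=True)
    enc = encode_dummies(train, mode="reference")
    enc_full = encode_dummies(train, mode="full")

    hr_rows = []
    for outcome in ("os", "css"):
        ts = two_stage_select_and_fit(enc, outcome)
        print(f"[{outcome.upper()}] two-stage kept {len(ts.feature_names)} "
              f"features: {', '.join(ts.feature_names)}")
        for feat, row in ts.hr_ci_p.iterrows():
            hr_rows.append({"outcome": outcome, "model": "two_stage",
                            "feature": feat, "HR": round(row.HR, 2),
                            "ci": f"{row.lower95:.2f}-{row.upper95:.2f}",
                            "p": round(row.p, 4)})
        fits = {"two_stage": ts}
        for pen in ("lasso", "ridge", "enet"):
            fit, path = fit_penalized_cox(enc_full, outcome, pen,
                                          seed=args.seed)
            fits[pen] = fit
            print(f"[{outcome.upper()}] {pen}-Cox: lambda* = "
                  f"{path.chosen_alpha:.6f}, {path.n_nonzero} nonzero of "
                  f"{len(fit.beta)}")
            if pen == "lasso":
                fits["cox_lasso"] = cox_with_lasso(enc_full, outcome, fit)
        for name, fit in fits.items():
            payload = {"family": fit.family, "outcome": outcome,
                       "features": fit.feature_names,
                       "beta": [float(b) for b in fit.beta],
                       "selection_trace": fit.selection_trace}
            (args.dir / f"fit_{name}_{outcome}.json").write_text(
                json.dumps(payload, indent=1, default=str))
    pd.DataFrame(hr_rows).to_csv(args.dir / "hazard_ratios.csv", index=False)


if __name__ == "__main__":
    main()
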