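"""Fill the cohort's missing categorical cells by the boosted-tree
multiple-imputation ensemble and score the result against the held truth.

Reports the proportion of falsely classified cells (PFC) per variable for
the ensemble and for the unconditional-mode baseline, and writes the
completed cohort used by all downstream stages.
"""

import argparse
from pathlib import Path

import pandas as pd

from gistnomo.impute import (ImputationConfig, evaluate_imputation,
                             misscatboosts_impute, mode_impute)
from gistnomo.synthetic import read_cohort, write_cohort


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=2)
    ap.add_argument("--chains", type=int, default=5)
    ap.add_argument("--dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    truth = read_cohort(args.dir / "cohort_truth.csv")
    gapped = read_cohort(args.dir / "cohort_gapped.csv")
    mask = pd.read_csv(args.dir / "cohort_mask.csv").astype(bool)

    cfg = ImputationConfig(n_chains=args.chains, max_passes=5,
                           seed=args.seed)
    result = misscatboosts_impute(gapped, cfg)
    write_cohort(result.completed_table, args.dir / "cohort_completed.csv")

    print("variable visit order:", ", ".join(result.variable_order))
    rows = []
    for var in mask.columns:
        m1 = evaluate_imputation(result.completed_table, truth,
                                 mask[[var]])["pfc"]
        m0 = evaluate_imputation(mode_impute(gapped), truth,
                                 mask[[var]])["pfc"]
        rows.append({"variable": var, "pfc_ensemble": m1, "pfc_mode": m0})
        print(f"  {var:24s} PFC {m1:.3f} (mode baseline {m0:.3f})")
    pd.DataFrame(rows).to_csv(args.dir / "imputation_scores.csv", index=False)


if __name__ == "__main__":
    main()
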