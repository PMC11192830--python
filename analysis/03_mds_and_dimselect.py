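"""Choose the MDS dimensionality by holdout cross-validation and fit the
final ordinal MDS configuration whose coordinates serve as cues.

Reads results/dissimilarity.csv + weights.csv; writes results/cues.csv,
results/mds_report.json and results/fit_indices.csv (the per-dimension
stress / CV / RSS / P / R^2 table).

Usage: python analysis/03_mds_and_dimselect.py [--seed 1] [--reps 100]
"""

import argparse
import json
import os

import pandas as pd

from rulexj import dimselect, mds, preprocess


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--reps", type=int, default=100,
                    help="cross-validation repetitions per dimensionality")
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()

    D = preprocess.read_dissimilarity(
        os.path.join(args.out_dir, "dissimilarity.csv"),
        os.path.join(args.out_dir, "weights.csv"),
    )
    dims = [1, 2, 3, 4, 5]
    cv = dimselect.cv_table(D, dims, reps=args.reps, seed=args.seed)
    rows = mds.fit_index_table(D, dims, n_starts=4, seed=args.seed)
    table = pd.DataFrame(
        {
            "dim": dims,
            "stress": [round(r.stress, 3) for r in rows],
            "cv_mean": [round(c.mean_r, 3) for c in cv],
            "cv_sd": [round(c.sd_r, 3) for c in cv],
            "rss": [round(r.rss, 3) for r in rows],
            "p": [r.p for r in rows],
            "r2": [round(r.r2, 3) for r in rows],
        }
    )
    table.to_csv(os.path.join(args.out_dir, "fit_indices.csv"), index=False)
    print(table.to_string(index=False))

    chosen = dimselect.choose_dims(cv)
    print(f"\nchosen dimensionality: {chosen}")
    sol = mds.fit_ordinal_mds(D, chosen, n_starts=8, seed=args.seed)
    mds.write_configuration(
        sol,
        os.path.join(args.out_dir, "cues.csv"),
        os.path.join(args.out_dir, "mds_report.json"),
    )
    with open(os.path.join(args.out_dir, "chosen_dim.json"), "w") as fh:
        json.dump({"chosen_dim": chosen, "stress": sol.stress}, fh)
    print(f"final configuration: stress {sol.stress:.3f} after {sol.n_iter} "
          f"iterations ({'converged' if sol.converged else 'NOT converged'})")


if __name__ == "__main__":
    main()
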