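"""Aggregate the rating table and build the normalized dissimilarity matrix.

Reads results/ratings.csv; writes results/dissimilarity.csv and
results/weights.csv.

Usage: python analysis/02_build_dissimilarity.py [--out-dir results]
"""

import argparse
import os

from rulexj import preprocess


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()

    ratings = preprocess.read_ratings(os.path.join(args.out_dir, "ratings.csv"))
    agg = preprocess.aggregate_ratings(ratings)
    D = preprocess.normalize_to_dissimilarity(agg)
    preprocess.write_dissimilarity(
        D,
        os.path.join(args.out_dir, "dissimilarity.csv"),
        os.path.join(args.out_dir, "weights.csv"),
    )
    obs = D.weights.sum() / 2
    print(f"{D.n} stimuli, {obs:.0f} observed pairs, "
          f"dissimilarities in [{D.values.min():.2f}, {D.values.max():.2f}]")


if __name__ == "__main__":
    main()
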