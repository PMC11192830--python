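"""Simulate the similarity-rating study: 32 stimuli in a 3-D latent space,
97 raters in balanced incomplete blocks of 4 (124 of the 496 pairs each),
7-point ratings that decrease with latent distance.

Writes results/ratings.csv, results/criterion.csv and a ground-truth
sidecar results/latent_truth.json.

Usage: python analysis/01_simulate_ratings.py [--seed 1] [--out-dir results]
"""

import argparse
import json
import os

import numpy as np

from rulexj import preprocess, synthetic


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()
    os.makedirs(args.out_dir, exist_ok=True)

    cfg = synthetic.make_latent_config(32, 3, "nonlinear", seed=args.seed)
    params = synthetic.SimRatingParams(n_raters=97, noise_sd=0.3, seed=args.seed + 1)
    ratings = synthetic.simulate_similarity_ratings(cfg, params)

    synthetic.write_ratings(ratings, os.path.join(args.out_dir, "ratings.csv"))
    synthetic.write_criterion(cfg, os.path.join(args.out_dir, "criterion.csv"))
    with open(os.path.join(args.out_dir, "latent_truth.json"), "w") as fh:
        json.dump(
            {
                "seed": args.seed,
                "d_true": 3,
                "coords": cfg.coords.tolist(),
                "noise_sd": params.noise_sd,
            },
            fh,
        )

    agg = preprocess.aggregate_ratings(ratings)
    print(f"{len(ratings)} ratings from 97 raters over {len(agg)} pairs")
    print(f"mean ratings per pair: {agg.n_ratings.mean():.2f} "
          f"(SD {agg.n_ratings.std():.2f})")
    print(f"criterion range: {cfg.criterion.min():.0f}-{cfg.criterion.max():.0f}")


if __name__ == "__main__":
    main()
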