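"""Fit the hierarchical Bayesian RulEx-J model to the simulated judgments.

Reads results/judgments.csv, results/cues.csv and results/exemplars.csv;
samples the posterior (4 chains), writes the group-level chains and a JSON
summary under results/posterior/, and prints the condition-level mixture
weights, the effect size delta, and the one-sided Savage-Dickey Bayes
factor for delta > 0.

Usage: python analysis/05_fit_rulexj.py [--seed 1] [--kept 5000]
"""

import argparse
import os

import pandas as pd

from rulexj import evaluate, model
from rulexj.mds import read_configuration


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--kept", type=int, default=5000)
    ap.add_argument("--burn-in", type=int, default=1000)
    ap.add_argument("--thin", type=int, default=1)
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()

    labels, cues_arr = read_configuration(os.path.join(args.out_dir, "cues.csv"))
    cues = model.CueMatrix(labels=labels, values=cues_arr)
    data = model.read_judgments(os.path.join(args.out_dir, "judgments.csv"))
    exdf = pd.read_csv(os.path.join(args.out_dir, "exemplars.csv"))
    idx = {s: i for i, s in enumerate(labels)}
    ex = model.ExemplarSet(
        labels=[str(s) for s in exdf.stim_id],
        cue_vectors=cues_arr[[idx[str(s)] for s in exdf.stim_id]],
        criterion=exdf.criterion.to_numpy(),
    )

    settings = model.SamplerSettings(
        n_chains=4, n_kept=args.kept, burn_in=args.burn_in, thin=args.thin,
        seed=args.seed,
    )
    post = model.sample_posterior(
        data, cues, ex, settings=settings,
        condition_order=("comparison", "direct"),
    )
    model.write_posterior(post, os.path.join(args.out_dir, "posterior"))

    summ = model.summarize_posterior(post).set_index("parameter")
    for name, label in (
        ("phi_mu_alpha_1", "alpha level, learning by comparison"),
        ("phi_mu_alpha_2", "alpha level, direct criterion learning"),
        ("delta", "effect size delta"),
    ):
        row = summ.loc[name]
        print(f"{label}: {row['mean']:.3f} "
              f"[{row.iloc[2]:.3f}, {row.iloc[3]:.3f}] 95% HDI")
    print(f"max split R-hat: {max(post.rhat.values()):.4f} "
          f"({'converged' if post.converged else 'NOT converged'})")

    bf = evaluate.sddr_bayes_factor(
        post.stacked("delta"), post.delta_prior, one_sided=True
    )
    print(f"Savage-Dickey {bf} (one-sided, delta > 0)")


if __name__ == "__main__":
    main()
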