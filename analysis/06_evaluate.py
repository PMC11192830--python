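"""Downstream evaluation: bridge-sampling model comparison, posterior
predictive checks, and judgment accuracy.

Reads the simulated study files under results/; refits the three models
(full mixture, rule-only, exemplar-only) per condition at a reduced MCMC
setting for the bridge-sampled comparison; writes
results/model_comparison.csv, results/ppc_by_condition.csv and
results/accuracy.csv.

Usage: python analysis/06_evaluate.py [--seed 1]
"""

import argparse
import os

import pandas as pd

from rulexj import evaluate, model
from rulexj.mds import read_configuration


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--kept", type=int, default=1500)
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

    # model comparison (Table-2-shaped output)
    res = evaluate.compare_models(
        data, cues, ex,
        settings=model.SamplerSettings(
            n_chains=2, n_kept=args.kept, burn_in=800, seed=args.seed + 1
        ),
        seed=args.seed + 2,
    )
    comp = pd.DataFrame(
        {
            "condition": [r.condition for r in res],
            "model_1": [r.model_pair[0] for r in res],
            "model_0": [r.model_pair[1] for r in res],
            "log_bf": [round(r.log_bf, 2) for r in res],
        }
    )
    comp.to_csv(os.path.join(args.out_dir, "model_comparison.csv"), index=False)
    print("model comparison, log(BF):")
    print(comp.to_string(index=False))

    # posterior predictive check on the full-model fit
    post = model.sample_posterior(
        data, cues, ex,
        settings=model.SamplerSettings(
            n_chains=2, n_kept=2000, burn_in=1000, seed=args.seed + 3
        ),
        condition_order=("comparison", "direct"),
    )
    ppc = evaluate.posterior_predictive_check(post, data, n_draws=200, seed=args.seed)
    ppc.condition_stats.round(3).to_csv(
        os.path.join(args.out_dir, "ppc_by_condition.csv"), index=False
    )
    print("\nposterior predictive check:")
    print(ppc.condition_stats.round(2).to_string(index=False))
    print(f"95% predictive-interval coverage: {ppc.coverage_95:.3f}")

    # judgment accuracy against the true criterion
    crit = pd.read_csv(os.path.join(args.out_dir, "criterion.csv"))
    acc = evaluate.judgment_accuracy(data, crit)
    acc.round(2).to_csv(os.path.join(args.out_dir, "accuracy.csv"), index=False)
    by_cond = acc.groupby("condition")[["rmse", "rmse_old", "rmse_new"]].mean()
    print("\njudgment accuracy (RMSE to the true criterion, by condition):")
    print(by_cond.round(2).to_string())


if __name__ == "__main__":
    main()
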