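"""Select a separating exemplar set and simulate the judgment experiment.

Reads results/cues.csv and results/criterion.csv; selects 12 exemplars
whose rule-only and exemplar-only predictions diverge (high between-model
RMSE) while both remain valid predictors of the criterion; simulates
2 x 39 participants whose judgments mix the two processes with
condition-level alpha .25 (learning by comparison) vs .15 (direct
criterion learning).

Writes results/judgments.csv, results/exemplars.csv and the ground-truth
sidecar results/judgment_truth.json.

Usage: python analysis/04_simulate_judgments.py [--seed 1] [--sigma-resp 5]
"""

import argparse
import os

import numpy as np
import pandas as pd

from rulexj import model, synthetic
from rulexj.mds import read_configuration


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--sigma-resp", type=float, default=5.0,
                    help="response noise SD in criterion units")
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()

    labels, cues_arr = read_configuration(os.path.join(args.out_dir, "cues.csv"))
    crit_df = pd.read_csv(os.path.join(args.out_dir, "criterion.csv"))
    crit = crit_df.set_index(crit_df.stim_id.astype(str)).criterion
    criterion = crit.loc[labels].to_numpy()

    sel = synthetic.select_exemplars(
        cues_arr, criterion, m=12, n_candidate_sets=2000, seed=args.seed + 2,
        relax_validity=True,
    )
    print(f"exemplar set {sorted(sel.indices.tolist())}")
    print(f"  between-model RMSE {sel.rmse_between_models:.2f}, "
          f"rule validity r={sel.rule_validity:.2f}, "
          f"exemplar validity r={sel.exemplar_validity:.2f}")

    cues = model.CueMatrix(labels=labels, values=cues_arr)
    ex = model.ExemplarSet(
        labels=[labels[i] for i in sel.indices],
        cue_vectors=cues_arr[sel.indices],
        criterion=criterion[sel.indices],
    )
    # the GCM sensitivity is interpretable per standardized cue-distance
    # unit; rescale it to the raw scale of the fitted MDS coordinates
    cue_scale = float(np.sqrt(np.mean(cues_arr.std(axis=0) ** 2)))
    params = synthetic.JudgeSimParams(
        seed=args.seed + 3, sigma_resp=args.sigma_resp, h=2.0 / cue_scale
    )
    data = synthetic.simulate_judgments(cues, ex, params)
    model.write_judgments(data, os.path.join(args.out_dir, "judgments.csv"))
    pd.DataFrame(
        {
            "stim_id": ex.labels,
            "criterion": ex.criterion,
        }
    ).to_csv(os.path.join(args.out_dir, "exemplars.csv"), index=False)
    synthetic.write_ground_truth(
        params, os.path.join(args.out_dir, "judgment_truth.json")
    )

    per = data.drop_duplicates("participant_id")
    print(f"{per.shape[0]} participants, {len(data)} trials")
    print("mean generating alpha by condition:",
          per.groupby("condition").alpha_true.mean().round(3).to_dict())


if __name__ == "__main__":
    main()
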