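import numpy as np
import pytest

from rulexj import model, preprocess, synthetic


@pytest.fixture(scope="session")
def latent32():
    """Study-scale latent space: 32 stimuli, 3 dimensions, nonlinear criterion."""
    return synthetic.make_latent_config(32, 3, "nonlinear", seed=42)


@pytest.fixture(scope="session")
def ratings32(latent32):
    params = synthetic.SimRatingParams(n_raters=97, noise_sd=0.3, seed=7)
    return synthetic.simulate_similarity_ratings(latent32, params)


@pytest.fixture(scope="session")
def dissim32(ratings32):
    return preprocess.dissimilarity_from_ratings(ratings32)


@pytest.fixture(scope="session")
def study(latent32):
    """A study-scale judgment dataset with known ground truth.

    Cues are the true latent coordinates (isolating the judgment model from
    MDS error); exemplars chosen by the selection procedure; 2 x 39
    participants with condition-level alpha .25 vs .15.
    """
    cfg = latent32
    cues = model.CueMatrix(labels=cfg.labels, values=cfg.coords)
    sel = synthetic.select_exemplars(
        cfg.coords, cfg.criterion, m=12, n_candidate_sets=300, seed=3
    )
    ex = model.ExemplarSet(
        labels=[cfg.labels[i] for i in sel.indices],
        cue_vectors=cfg.coords[sel.indices],
        criterion=cfg.criterion[sel.indices],
    )
    params = synthetic.JudgeSimParams(seed=11)
    data = synthetic.simulate_judgments(cues, ex, params)
    return {"config": cfg, "cues": cues, "ex": ex, "params": params, "data": data}
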