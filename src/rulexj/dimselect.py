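"""Choose the MDS dimensionality by holdout cross-validation over matrix cells.

Per repetition, a fraction of the observed unordered pairs is held out
(weight set to zero), an ordinal MDS solution is fitted to the remainder,
and the held-out dissimilarities are predicted by the fitted configuration
distances; the criterion is the Pearson correlation between predictions and
held-out values, averaged over repetitions.  Dimensionality is then chosen
by a one-SD parsimony rule: the smallest dimensionality whose mean
correlation lies within one standard deviation of the best one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from rulexj.mds import DissimilarityMatrix, fit_ordinal_mds

__all__ = ["CVResult", "crossvalidate_dim", "choose_dims", "cv_table"]

log = logging.getLogger(__name__)


@dataclass
class CVResult:
    """Cross-validation outcome for one dimensionality."""

    dim: int
    mean_r: float
    sd_r: float
    reps: int
    holdout_frac: float
    n_redraws: int = 0


def crossvalidate_dim(
    D: DissimilarityMatrix,
    dim: int,
    holdout_frac: float = 0.2,
    reps: int = 500,
    seed: int = 0,
    n_starts: int = 2,
    max_iter: int = 500,
    tol: float = 1e-6,
    max_redraws: int = 50,
) -> CVResult:
    """Holdout cross-validation of an ordinal MDS fit at one dimensionality.

    Holdout sampling is over observed unordered pairs (upper-triangle cells),
    keeping the matrix symmetric.  Repetitions whose retained observation
    graph is disconnected are redrawn (counted in ``n_redraws``).
    """
    if not (0 < holdout_frac <= 0.5):
        raise ValueError("holdout_frac must be in (0, 0.5]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if dim >= D.n:
        raise ValueError("dim must be smaller than the number of stimuli")
    iu, ju = D.observed_pairs()
    K = iu.size
    n_hold = int(np.floor(holdout_frac * K))
    if n_hold < 2:
        raise ValueError("holdout too small to compute a correlation")
    rng = np.random.default_rng(seed)
    rs = []
    n_redraws = 0
    while len(rs) < reps:
        hold = rng.choice(K, size=n_hold, replace=False)
        Dtrain = D.copy()
        Dtrain.weights[iu[hold], ju[hold]] = 0.0
        Dtrain.weights[ju[hold], iu[hold]] = 0.0
        try:
            sol = fit_ordinal_mds(
                Dtrain,
                dim,
                n_starts=n_starts,
                max_iter=max_iter,
                tol=tol,
                seed=int(rng.integers(2**31)),
            )
        except ValueError as err:
            if "disconnected" in str(err):
                n_redraws += 1
                if n_redraws > max_redraws:
                    raise ValueError(
                        "holdout resampling kept disconnecting the "
                        "observation graph"
                    ) from err
                log.info("redrawing disconnected holdout (%d)", n_redraws)
                continue
            raise
        dist = cdist(sol.coords, sol.coords)
        pred = dist[iu[hold], ju[hold]]
        true = D.values[iu[hold], ju[hold]]
        rs.append(pearsonr(pred, true)[0])
    rs = np.asarray(rs)
    return CVResult(
        dim=dim,
        mean_r=float(rs.mean()),
        sd_r=float(rs.std(ddof=1)) if reps > 1 else 0.0,
        reps=reps,
        holdout_frac=holdout_frac,
        n_redraws=n_redraws,
    )


def choose_dims(results: list[CVResult]) -> int:
    """One-SD parsimony rule over cross-validation results.

    Returns the smallest dimensionality whose mean correlation exceeds
    (best mean - SD of the best dimensionality); with a zero SD this reduces
    to the smallest dimensionality attaining the maximum.
    """
    if not results:
        raise ValueError("empty result list")
    results = sorted(results, key=lambda r: r.dim)
    means = np.array([r.mean_r for r in results])
    best_i = int(np.argmax(means))
    sd_best = results[best_i].sd_r
    if sd_best > 0:
        eligible = means > means[best_i] - sd_best
    else:
        eligible = means >= means[best_i]
    return results[int(np.flatnonzero(eligible)[0])].dim


def cv_table(
    D: DissimilarityMatrix,
    dims_list: list[int],
    holdout_frac: float = 0.2,
    reps: int = 500,
    seed: int = 0,
    **fit_kwargs,
) -> list[CVResult]:
    """Cross-validate a list of dimensionalities with a shared base seed."""
    return [
        crossvalidate_dim(
            D, dim, holdout_frac=holdout_frac, reps=reps,
            seed=seed + 1000 * dim, **fit_kwargs,
        )
        for dim in dims_list
    ]
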