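"""Ordinal (non-metric) multidimensional scaling by weighted stress majorization.

Given a symmetric matrix of normalized dissimilarities with observation
weights (weight 0 marks an unobserved or held-out cell), the fitting routine
alternates two steps until the relative change in Stress-1 falls below a
tolerance:

* a *disparity* update: optimal-scaling values ``dhat`` obtained by weighted
  monotone (isotonic) regression of the current configuration distances onto
  the rank order of the dissimilarities, rescaled so that the weighted sum of
  squared disparities equals the weighted sum of squared distances;
* a *configuration* update by the weighted Guttman transform (SMACOF
  majorization), which cannot increase the majorized stress.

The resulting low-dimensional coordinates serve as continuous cue values for
the judgment models downstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

__all__ = [
    "DissimilarityMatrix",
    "MDSSolution",
    "FitIndexRow",
    "monotone_regression",
    "fit_ordinal_mds",
    "stress1",
    "config_distances",
    "fit_index_table",
    "write_configuration",
    "read_configuration",
]


@dataclass
class DissimilarityMatrix:
    """Symmetric normalized dissimilarities in [0, 1] with observation weights.

    ``weights[i, j] == 0`` marks an unobserved (or held-out) cell; such cells
    take no part in fitting or normalization.
    """

    values: np.ndarray
    weights: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or self.weights.shape != (n, n):
            raise ValueError("values and weights must be square and congruent")
        if len(self.labels) != n:
            raise ValueError("labels length must match matrix size")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def observed_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of observed upper-triangle cells."""
        iu, ju = np.triu_indices(self.n, k=1)
        keep = self.weights[iu, ju] > 0
        return iu[keep], ju[keep]

    def copy(self) -> "DissimilarityMatrix":
        return DissimilarityMatrix(
            self.values.copy(), self.weights.copy(), list(self.labels)
        )


@dataclass
class MDSSolution:
    """A fitted ordinal MDS configuration.

    ``coords`` is the column-centered n x d configuration; ``disparities``
    holds the optimally scaled values for the observed pairs in the order
    given by ``pair_index`` (upper-triangle row/col indices).
    """

    coords: np.ndarray
    disparities: np.ndarray
    stress: float
    n_iter: int
    converged: bool
    seed: int
    labels: list[str] = field(default_factory=list)
    pair_index: tuple[np.ndarray, np.ndarray] | None = None
    stress_history: np.ndarray | None = None


@dataclass
class FitIndexRow:
    """One row of the dimensionality fit-index table."""

    dim: int
    stress: float
    rss: float
    p: int
    r2: float


def monotone_regression(
    targets: np.ndarray, order: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Weighted least-squares fit to ``targets`` that is weakly increasing
    along ``order``.

    ``order`` is a permutation of indices; the returned array (aligned with
    ``targets``) is weakly increasing when read in that order.  Ties in the
    quantity that produced ``order`` are handled upstream (primary approach:
    tied inputs may receive different fitted values).
    """
    targets = np.asarray(targets, dtype=float)
    order = np.asarray(order, dtype=int)
    if weights is None:
        weights = np.ones_like(targets)
    weights = np.asarray(weights, dtype=float)
    if targets.shape != weights.shape or order.shape != targets.shape:
        raise ValueError("targets, order and weights must have equal length")
    if not np.any(weights > 0):
        raise ValueError("weights must not be all zero")
    fitted_sorted = _pava(targets[order], weights[order])
    out = np.empty_like(fitted_sorted)
    out[order] = fitted_sorted
    return out


def _pava_py(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators for a weakly increasing fit (stack algorithm)."""
    n = y.size
    means = np.empty(n)
    wsum = np.empty(n)
    count = np.empty(n, dtype=np.int64)
    top = -1
    for i in range(n):
        top += 1
        means[top] = y[i]
        wsum[top] = w[i]
        count[top] = 1
        while top > 0 and means[top - 1] > means[top]:
            tw = wsum[top - 1] + wsum[top]
            if tw > 0:
                means[top - 1] = (
                    means[top - 1] * wsum[top - 1] + means[top] * wsum[top]
                ) / tw
            wsum[top - 1] = tw
            count[top - 1] += count[top]
            top -= 1
    return np.repeat(means[: top + 1], count[: top + 1])


try:  # the PAVA inner loop is the fitting hot spot; JIT it when possible
    from numba import njit as _njit

    _pava = _njit(cache=True)(_pava_py)
except ImportError:  # pragma: no cover
    _pava = _pava_py


def config_distances(coords: np.ndarray) -> np.ndarray:
    """Euclidean interpoint distance matrix of a configuration."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    return cdist(coords, coords)


def stress1(
    coords: np.ndarray, disparities: np.ndarray, weights: np.ndarray
) -> float:
    """Kruskal's Stress-1 of a configuration against disparities.

    ``disparities`` and ``weights`` are full n x n symmetric matrices;
    only cells with positive weight enter the sums:

        stress1 = sqrt( sum w (d - dhat)^2 / sum w d^2 )
    """
    d = config_distances(coords)
    w = np.asarray(weights, dtype=float)
    dhat = np.asarray(disparities, dtype=float)
    denom = float(np.sum(w * d**2))
    if denom <= 0:
        raise ValueError("all configuration distances are zero under the weights")
    num = float(np.sum(w * (d - dhat) ** 2))
    return float(np.sqrt(num / denom))


def _check_connected(n: int, iu: np.ndarray, ju: np.ndarray, labels: list[str]) -> None:
    g = coo_matrix((np.ones(iu.size), (iu, ju)), shape=(n, n))
    ncomp, member = connected_components(g, directed=False)
    if ncomp > 1:
        comps = [
            [labels[i] for i in np.flatnonzero(member == c)] for c in range(ncomp)
        ]
        raise ValueError(
            f"observation graph is disconnected into {ncomp} components: {comps}"
        )


def _torgerson_init(D: DissimilarityMatrix, dims: int) -> np.ndarray:
    """Classical (Torgerson) scaling of the observed matrix; unobserved cells
    are imputed with the mean observed dissimilarity (initialization only)."""
    vals = D.values.copy()
    obs = D.weights > 0
    off = ~np.eye(D.n, dtype=bool)
    fill = vals[obs & off].mean() if np.any(obs & off) else 0.5
    vals[~obs & off] = fill
    np.fill_diagonal(vals, 0.0)
    d2 = vals**2
    J = np.eye(D.n) - np.ones((D.n, D.n)) / D.n
    B = -0.5 * J @ d2 @ J
    evals, evecs = np.linalg.eigh(B)
    idx = np.argsort(evals)[::-1][:dims]
    lam = np.clip(evals[idx], 0.0, None)
    return evecs[:, idx] * np.sqrt(lam)


def _fit_single(
    delta: np.ndarray,
    w: np.ndarray,
    iu: np.ndarray,
    ju: np.ndarray,
    X0: np.ndarray,
    max_iter: int,
    tol: float,
    ties: str,
) -> tuple[np.ndarray, np.ndarray, float, int, bool, np.ndarray]:
    n = X0.shape[0]
    wv = w[iu, ju]
    dv = delta[iu, ju]

    # Laplacian of the weight matrix and its pseudo-inverse (fixed per fit)
    W = np.zeros((n, n))
    W[iu, ju] = wv
    W[ju, iu] = wv
    V = np.diag(W.sum(axis=1)) - W
    Vpinv = np.linalg.pinv(V)

    # secondary tie approach pools cells with exactly equal dissimilarity
    if ties == "secondary":
        _, tie_group = np.unique(dv, return_inverse=True)
    elif ties != "primary":
        raise ValueError("ties must be 'primary' or 'secondary'")

    X = X0 - X0.mean(axis=0)
    stress_prev = np.inf
    history = []
    dist = cdist(X, X)[iu, ju]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # disparity update: isotonic fit of distances in the dissimilarity
        # rank order; primary approach breaks ties by the current distances
        if ties == "primary":
            order = np.lexsort((dist, dv))
            dhat = monotone_regression(dist, order, wv)
        else:
            nb = np.bincount(tie_group, weights=wv)
            gm = np.zeros_like(nb)
            np.add.at(gm, tie_group, wv * dist)
            with np.errstate(invalid="ignore"):
                gm = np.where(nb > 0, gm / np.maximum(nb, 1e-300), 0.0)
            fitted = _pava(gm, nb)
            dhat = fitted[tie_group]
        ss_d = float(np.sum(wv * dist**2))
        ss_h = float(np.sum(wv * dhat**2))
        if ss_h > 0:
            dhat = dhat * np.sqrt(ss_d / ss_h)

        # Guttman transform with the current disparities
        ratio = np.where(dist > 1e-12, dhat / np.maximum(dist, 1e-12), 0.0)
        B = np.zeros((n, n))
        B[iu, ju] = -wv * ratio
        B[ju, iu] = B[iu, ju]
        np.fill_diagonal(B, -B.sum(axis=1))
        X = Vpinv @ (B @ X)
        X -= X.mean(axis=0)

        dist = cdist(X, X)[iu, ju]
        num = float(np.sum(wv * (dist - dhat) ** 2))
        den = float(np.sum(wv * dist**2))
        stress = np.sqrt(num / den) if den > 0 else np.inf
        history.append(stress)
        if stress_prev - stress < tol * max(stress_prev, 1e-12):
            converged = True
            stress_prev = stress
            break
        stress_prev = stress

    dhat_final = dhat
    return X, dhat_final, float(stress_prev), it, converged, np.array(history)


def fit_ordinal_mds(
    D: DissimilarityMatrix,
    dims: int,
    n_starts: int = 8,
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int = 0,
    ties: str = "primary",
) -> MDSSolution:
    """Fit an ordinal MDS configuration by weighted stress majorization.

    Parameters
    ----------
    D : DissimilarityMatrix
        Normalized dissimilarities with observation weights (0 = held out).
    dims : int
        Dimensionality of the configuration, ``1 <= dims < n``.
    n_starts : int
        Number of starts; the first uses classical (Torgerson) scaling of the
        observed matrix, the rest are random standard-normal configurations.
        The start with the lowest final Stress-1 wins.
    ties : {"primary", "secondary"}
        Primary approach unties tied dissimilarities freely (default);
        secondary forces tied cells to share a disparity.
    """
    if dims < 1:
        raise ValueError("dims must be >= 1")
    if dims >= D.n:
        raise ValueError("dims must be smaller than the number of stimuli")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    iu, ju = D.observed_pairs()
    if iu.size == 0:
        raise ValueError("no observed pairs")
    _check_connected(D.n, iu, ju, D.labels)

    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        if s == 0:
            X0 = _torgerson_init(D, dims)
            if not np.any(np.abs(X0) > 1e-12):  # degenerate classical start
                X0 = rng.standard_normal((D.n, dims))
        else:
            X0 = rng.standard_normal((D.n, dims))
        fit = _fit_single(D.values, D.weights, iu, ju, X0, max_iter, tol, ties)
        if best is None or fit[2] < best[2]:
            best = fit
    X, dhat, stress, n_iter, converged, history = best

    _warn_degenerate(X, D, iu, ju)
    dh_full = np.zeros((D.n, D.n))
    dh_full[iu, ju] = dhat
    dh_full[ju, iu] = dhat
    return MDSSolution(
        coords=X,
        disparities=dhat,
        stress=float(stress1(X, dh_full, D.weights)),
        n_iter=n_iter,
        converged=converged,
        seed=seed,
        labels=list(D.labels),
        pair_index=(iu, ju),
        stress_history=history,
    )


def _warn_degenerate(
    X: np.ndarray, D: DissimilarityMatrix, iu: np.ndarray, ju: np.ndarray
) -> None:
    dist = cdist(X, X)[iu, ju]
    med = np.median(D.values[iu, ju])
    bad = (dist < 1e-8) & (D.values[iu, ju] > med)
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} point pair(s) collapsed despite large "
            "dissimilarity; the solution may be degenerate",
            RuntimeWarning,
            stacklevel=3,
        )


def fit_index_table(
    D: DissimilarityMatrix,
    dims_list: list[int],
    n_starts: int = 8,
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int = 0,
    rss_target: str = "dissimilarity",
) -> list[FitIndexRow]:
    """Fit indices (stress, RSS, parameter count, R^2) per dimensionality.

    ``rss_target='dissimilarity'`` computes the residual sum of squares of the
    configuration distances against the observed dissimilarities; the
    alternative ``'disparity'`` uses the optimally scaled disparities instead.
    R^2 is the squared Pearson correlation between configuration distances and
    observed dissimilarities.
    """
    if rss_target not in ("dissimilarity", "disparity"):
        raise ValueError("rss_target must be 'dissimilarity' or 'disparity'")
    rows = []
    for dim in dims_list:
        sol = fit_ordinal_mds(
            D, dim, n_starts=n_starts, max_iter=max_iter, tol=tol, seed=seed
        )
        iu, ju = sol.pair_index
        dist = cdist(sol.coords, sol.coords)[iu, ju]
        wv = D.weights[iu, ju]
        target = D.values[iu, ju] if rss_target == "dissimilarity" else sol.disparities
        # the ordinal configuration's overall scale is arbitrary, so residuals
        # are taken at the least-squares scaling of distances onto the target
        b = float(np.sum(wv * dist * target) / np.sum(wv * dist**2))
        rss = float(np.sum(wv * (b * dist - target) ** 2))
        r = np.corrcoef(dist, D.values[iu, ju])[0, 1]
        rows.append(
            FitIndexRow(
                dim=dim,
                stress=sol.stress,
                rss=rss,
                p=D.n * dim,
                r2=float(r**2),
            )
        )
    return rows


def write_configuration(sol: MDSSolution, path: str, report_path: str | None = None) -> None:
    """Write the configuration as delimited text (stim_id, dim_1..dim_d);
    this file is the downstream cue matrix.  Optionally write a JSON fit
    report."""
    d = sol.coords.shape[1]
    df = pd.DataFrame(sol.coords, columns=[f"dim_{k + 1}" for k in range(d)])
    df.insert(0, "stim_id", sol.labels if sol.labels else range(len(df)))
    df.to_csv(path, index=False)
    if report_path is not None:
        with open(report_path, "w") as fh:
            json.dump(
                {
                    "stress": sol.stress,
                    "n_iter": sol.n_iter,
                    "converged": sol.converged,
                    "seed": sol.seed,
                    "dims": d,
                },
                fh,
                indent=2,
            )


def read_configuration(path: str) -> tuple[list[str], np.ndarray]:
    """Read a configuration/cue-matrix file; returns (labels, coords)."""
    df = pd.read_csv(path)
    labels = [str(x) for x in df["stim_id"]]
    coords = df[[c for c in df.columns if c.startswith("dim_")]].to_numpy(float)
    return labels, coords
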