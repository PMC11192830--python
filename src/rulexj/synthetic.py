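"""Synthetic study generators with known ground truth.

The pipeline assumes that (i) pairwise similarity ratings are noisy monotone
decreasing functions of distances in a low-dimensional latent stimulus space,
collected under a balanced incomplete block design in which small groups of
raters jointly cover all pairs, and (ii) numerical judgments arise from the
RulEx-J mixture of a linear rule and an exemplar (GCM) process, with
per-participant mixture weights drawn from condition-specific probit-normal
distributions and additive Gaussian response noise.  This module generates
data with exactly that structure, so every downstream stage can be exercised
against known truth.

Default geometry mirrors the study scale: 32 stimuli in a 3-dimensional
latent space, a 7-point rating scale, rater groups of 4 (124 pairs each out
of 496), 12 exemplars, and 39 participants per condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import ndtr
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from rulexj.model import (
    CueMatrix,
    ExemplarSet,
    exemplar_prediction,
    rule_prediction,
)

__all__ = [
    "LatentConfig",
    "SimRatingParams",
    "JudgeSimParams",
    "ExemplarSelection",
    "make_latent_config",
    "assign_pairs_bibd",
    "simulate_similarity_ratings",
    "select_exemplars",
    "training_pairs",
    "simulate_judgments",
    "write_ratings",
    "write_criterion",
    "stimulus_labels",
]


def stimulus_labels(n: int) -> list[str]:
    """Zero-padded stimulus ids so lexicographic and numeric order agree."""
    width = len(str(n - 1))
    return [f"s{i:0{width}d}" for i in range(n)]


@dataclass
class LatentConfig:
    """A latent stimulus space with a criterion value per stimulus."""

    coords: np.ndarray
    criterion: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.criterion = np.asarray(self.criterion, dtype=float)
        if self.coords.shape[0] < 3:
            raise ValueError("need at least 3 stimuli")
        if self.coords.shape[1] < 1:
            raise ValueError("need at least 1 latent dimension")
        if not np.all(np.isfinite(self.criterion)):
            raise ValueError("criterion must be finite")
        self.coords = self.coords - self.coords.mean(axis=0)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def labels(self) -> list[str]:
        return stimulus_labels(self.n)


@dataclass
class SimRatingParams:
    """Settings for similarity-rating simulation."""

    n_raters: int = 97
    scale_levels: int = 7
    noise_sd: float = 0.5
    group_size: int = 4
    seed: int = 0
    link: str = "linear"

    def __post_init__(self) -> None:
        if self.scale_levels < 2:
            raise ValueError("scale_levels must be >= 2")
        if self.n_raters < 1:
            raise ValueError("n_raters must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.link not in ("linear", "exponential"):
            raise ValueError("link must be 'linear' or 'exponential'")


@dataclass
class JudgeSimParams:
    """Ground-truth parameters for RulEx-J judgment simulation.

    ``mu_alpha`` are the condition-level probit means; the defaults put the
    condition-level alpha at .25 (condition 1) versus .15 (condition 2), and
    ``sigma_theta`` is set so the standardized difference
    (mu_alpha_1 - mu_alpha_2) / sigma_theta is about 2.3.
    """

    mu_alpha: tuple[float, float] = (-0.6745, -1.0364)
    sigma_theta: float = 0.157
    beta0: float = 0.0
    beta: np.ndarray | None = None
    h: float = 2.0
    sigma_resp: float = 15.0
    n_per_condition: int = 39
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_theta <= 0 or self.h <= 0 or self.sigma_resp <= 0:
            raise ValueError("scale parameters must be strictly positive")
        if self.n_per_condition < 1:
            raise ValueError("n_per_condition must be >= 1")
        if self.beta is not None:
            self.beta = np.asarray(self.beta, dtype=float)


def make_latent_config(
    n_stimuli: int = 32,
    d_true: int = 3,
    criterion_kind: str = "nonlinear",
    seed: int = 0,
    criterion_range: tuple[float, float] = (24.0, 125.0),
) -> LatentConfig:
    """Draw a latent configuration and a criterion over it.

    Coordinates are standard-normal, column-centered.  The criterion is an
    affine map of the coordinates (``linear``) or an affine map plus
    pairwise-product interaction terms (``nonlinear``, the harder regime
    typical of natural criteria such as flight speed), rescaled into
    ``criterion_range`` (default 24-125, criterion units).
    """
    if n_stimuli < 3 or d_true < 1:
        raise ValueError("need n_stimuli >= 3 and d_true >= 1")
    if criterion_kind not in ("linear", "nonlinear"):
        raise ValueError("criterion_kind must be 'linear' or 'nonlinear'")
    rng = np.random.default_rng(seed)
    coords = rng.standard_normal((n_stimuli, d_true))
    coords -= coords.mean(axis=0)
    w = rng.uniform(0.5, 1.5, size=d_true) * rng.choice([-1.0, 1.0], size=d_true)
    raw = coords @ w
    if criterion_kind == "nonlinear":
        iu, ju = np.triu_indices(d_true)
        inter = coords[:, iu] * coords[:, ju]
        wi = rng.uniform(0.3, 1.0, size=inter.shape[1]) * rng.choice(
            [-1.0, 1.0], size=inter.shape[1]
        )
        raw = raw + inter @ wi
    lo, hi = criterion_range
    span = raw.max() - raw.min()
    if span <= 0:
        raise ValueError("degenerate criterion (zero range)")
    criterion = lo + (raw - raw.min()) / span * (hi - lo)
    return LatentConfig(coords=coords, criterion=criterion, seed=seed)


def assign_pairs_bibd(
    n_stimuli: int, group_size: int = 4, n_raters: int = 97, seed: int = 0
) -> dict[int, list[tuple[int, int]]]:
    """Assign stimulus pairs to raters in a balanced incomplete block design.

    Raters are processed in consecutive groups of ``group_size``; within each
    group the K = n(n-1)/2 unordered pairs are randomly partitioned into
    ``group_size`` near-equal shares (exactly equal when group_size divides
    K), so every complete group jointly covers all pairs.  Pair order per
    rater is randomized.
    """
    if n_raters < 1 or group_size < 1:
        raise ValueError("n_raters and group_size must be >= 1")
    if n_stimuli < 2:
        raise ValueError("need at least 2 stimuli")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n_stimuli, k=1)
    K = iu.size
    assignment: dict[int, list[tuple[int, int]]] = {}
    rater = 0
    while rater < n_raters:
        perm = rng.permutation(K)
        shares = np.array_split(perm, group_size)
        for share in shares:
            if rater >= n_raters:
                break
            share = share[rng.permutation(share.size)]
            assignment[rater] = [(int(iu[k]), int(ju[k])) for k in share]
            rater += 1
    return assignment


def simulate_similarity_ratings(
    config: LatentConfig, params: SimRatingParams
) -> pd.DataFrame:
    """Generate a long-format rating table from latent distances.

    Each assigned pair's Euclidean latent distance is mapped monotonically
    onto the rating scale (largest distance -> 1, smallest -> scale_levels;
    linear map by default, exponential behind the ``link`` flag), perturbed
    with Gaussian noise, rounded half-up and clamped to [1, scale_levels].
    """
    D = cdist(config.coords, config.coords)
    iu, ju = np.triu_indices(config.n, k=1)
    dmin, dmax = D[iu, ju].min(), D[iu, ju].max()
    if dmax - dmin <= 0:
        raise ValueError("degenerate configuration: all latent distances equal")
    L = params.scale_levels
    rng = np.random.default_rng(params.seed)
    assignment = assign_pairs_bibd(
        config.n, params.group_size, params.n_raters,
        seed=rng.integers(2**31),
    )
    labels = config.labels
    rows_r, rows_a, rows_b, rows_v = [], [], [], []
    for rater, pairs in assignment.items():
        idx = np.array(pairs)
        d = D[idx[:, 0], idx[:, 1]]
        u = (d - dmin) / (dmax - dmin)
        if params.link == "linear":
            sim = L - (L - 1) * u
        else:
            sim = 1 + (L - 1) * (np.exp(-3 * u) - np.exp(-3)) / (1 - np.exp(-3))
        sim = sim + rng.normal(0.0, params.noise_sd, size=sim.shape)
        rating = np.clip(np.floor(sim + 0.5), 1, L).astype(int)
        rows_r.append(np.full(len(pairs), rater))
        rows_a.append(idx[:, 0])
        rows_b.append(idx[:, 1])
        rows_v.append(rating)
    lab = np.array(labels)
    return pd.DataFrame(
        {
            "rater_id": np.concatenate(rows_r),
            "stim_a": lab[np.concatenate(rows_a)],
            "stim_b": lab[np.concatenate(rows_b)],
            "rating": np.concatenate(rows_v),
        }
    )


def training_pairs(
    criterion: np.ndarray, decimals: int = 1
) -> list[tuple[int, int]]:
    """All unordered exemplar pairs usable as comparison training trials:
    pairs whose criterion values are tied (after rounding to ``decimals``)
    are removed, since relative feedback is undefined for them."""
    c = np.round(np.asarray(criterion, dtype=float), decimals)
    m = c.size
    return [(i, j) for i in range(m) for j in range(i + 1, m) if c[i] != c[j]]


@dataclass
class ExemplarSelection:
    """Result of the exemplar-set search."""

    indices: np.ndarray
    rmse_between_models: float
    rule_validity: float
    exemplar_validity: float
    criterion_range_fraction: float
    n_candidates: int
    n_admissible: int


def _fit_exemplar_h(
    cues: np.ndarray, criterion: np.ndarray, idx: np.ndarray
) -> tuple[float, np.ndarray]:
    """1-D fit of the GCM sensitivity h; returns (h, predictions for all)."""
    ex = ExemplarSet(
        labels=[str(i) for i in idx],
        cue_vectors=cues[idx],
        criterion=criterion[idx],
    )

    def loss(log_h: float) -> float:
        pred = exemplar_prediction(cues, ex, float(np.exp(log_h)))
        return float(np.mean((pred - criterion) ** 2))

    res = minimize_scalar(loss, bounds=(-4.0, 4.0), method="bounded")
    h = float(np.exp(res.x))
    return h, np.asarray(exemplar_prediction(cues, ex, h))


def select_exemplars(
    cues: np.ndarray,
    criterion: np.ndarray,
    m: int = 12,
    n_candidate_sets: int = 2000,
    min_validity: float = 0.7,
    seed: int = 0,
    min_range_frac: float = 0.7,
    exhaustive: bool = False,
    relax_validity: bool = False,
) -> ExemplarSelection:
    """Search for an exemplar set that separates rule from exemplar process.

    Among random m-subsets (or all subsets with ``exhaustive=True``) a
    rule-only model (least squares of the criterion on the cues over the
    exemplars) and an exemplar-only model (equal-weight GCM, h fit by 1-D
    optimization) each predict all stimuli.  Sets whose model predictions
    correlate with the criterion below ``min_validity``, or whose exemplar
    criterion range is below ``min_range_frac`` of the full range, are
    discarded; among the survivors the set maximizing the RMSE between the
    two models' predictions is returned together with its statistics.

    With ``relax_validity=True`` an empty candidate pool lowers
    ``min_validity`` in steps of 0.05 (down to 0.5, logged) before giving
    up -- some latent criteria admit no set at the requested validity.
    """
    cues = np.atleast_2d(np.asarray(cues, dtype=float))
    criterion = np.asarray(criterion, dtype=float)
    n = cues.shape[0]
    if not (0 < m < n):
        raise ValueError("need 0 < m < n")
    rng = np.random.default_rng(seed)
    if exhaustive:
        from itertools import combinations

        candidates = [np.array(c) for c in combinations(range(n), m)]
    else:
        candidates = [
            np.sort(rng.choice(n, size=m, replace=False))
            for _ in range(n_candidate_sets)
        ]
    full_range = criterion.max() - criterion.min()
    Xd = np.column_stack([np.ones(n), cues])

    best: ExemplarSelection | None = None
    n_admissible = 0
    for idx in candidates:
        coef, *_ = np.linalg.lstsq(Xd[idx], criterion[idx], rcond=None)
        rule_pred = Xd @ coef
        _, ex_pred = _fit_exemplar_h(cues, criterion, idx)
        r_rule = pearsonr(rule_pred, criterion)[0]
        r_ex = pearsonr(ex_pred, criterion)[0]
        rng_frac = (criterion[idx].max() - criterion[idx].min()) / full_range
        if r_rule < min_validity or r_ex < min_validity or rng_frac < min_range_frac:
            continue
        n_admissible += 1
        rmse = float(np.sqrt(np.mean((rule_pred - ex_pred) ** 2)))
        if best is None or rmse > best.rmse_between_models:
            best = ExemplarSelection(
                indices=idx,
                rmse_between_models=rmse,
                rule_validity=float(r_rule),
                exemplar_validity=float(r_ex),
                criterion_range_fraction=float(rng_frac),
                n_candidates=len(candidates),
                n_admissible=0,
            )
    if best is None:
        if relax_validity and min_validity - 0.05 >= 0.5 - 1e-9:
            import logging

            logging.getLogger(__name__).warning(
                "no admissible exemplar set at min_validity=%.2f; retrying "
                "at %.2f", min_validity, min_validity - 0.05,
            )
            return select_exemplars(
                cues, criterion, m=m, n_candidate_sets=n_candidate_sets,
                min_validity=min_validity - 0.05, seed=seed,
                min_range_frac=min_range_frac, exhaustive=exhaustive,
                relax_validity=True,
            )
        raise ValueError(
            "no admissible exemplar set: every candidate failed the validity "
            "or criterion-range filter"
        )
    best.n_admissible = n_admissible
    return best


def simulate_judgments(
    cues: CueMatrix | np.ndarray,
    exemplars: ExemplarSet,
    params: JudgeSimParams,
    design: dict[str, list[str]] | None = None,
    conditions: tuple[str, str] = ("comparison", "direct"),
) -> pd.DataFrame:
    """Simulate a judgment table from the RulEx-J mixture.

    Participant *i* in condition *j* receives
    ``theta_i ~ Normal(mu_alpha[j], sigma_theta^2)``, ``alpha_i =
    Phi(theta_i)``, and responds to each designed stimulus with
    ``alpha_i * J_R + (1 - alpha_i) * J_E + Normal(0, sigma_resp^2)``.
    By default every participant judges every stimulus.  The hidden
    ground-truth mixture weight is recorded in the ``alpha_true`` column.
    """
    if not isinstance(cues, CueMatrix):
        cues = CueMatrix(labels=stimulus_labels(len(cues)), values=cues)
    if params.beta is not None:
        beta0, beta = params.beta0, params.beta
    else:
        # default true rule: least squares of the exemplar criterion on the
        # exemplar cues (the best linear rule abstractable from training)
        Xd = np.column_stack([np.ones(exemplars.m), exemplars.cue_vectors])
        coef, *_ = np.linalg.lstsq(Xd, exemplars.criterion, rcond=None)
        beta0, beta = float(coef[0]), coef[1:]
    rng = np.random.default_rng(params.seed)
    jr_all = rule_prediction(cues.values, beta0, beta)
    je_all = np.asarray(exemplar_prediction(cues.values, exemplars, params.h))
    label_idx = {s: i for i, s in enumerate(cues.labels)}
    old = set(exemplars.labels)

    rows = []
    pid = 0
    for j, cond in enumerate(conditions):
        for _ in range(params.n_per_condition):
            pname = f"p{pid:03d}"
            theta = rng.normal(params.mu_alpha[j], params.sigma_theta)
            alpha = float(ndtr(theta))
            stim_list = (
                design[pname] if design is not None else list(cues.labels)
            )
            for s in stim_list:
                k = label_idx[s]
                mu = alpha * jr_all[k] + (1 - alpha) * je_all[k]
                resp = mu + rng.normal(0.0, params.sigma_resp)
                rows.append(
                    (pname, cond, s, s in old, resp, alpha)
                )
            pid += 1
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "condition",
            "stim_id",
            "is_old",
            "response",
            "alpha_true",
        ],
    )


def write_ratings(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False)


def write_criterion(config: LatentConfig, path: str) -> None:
    pd.DataFrame({"stim_id": config.labels, "criterion": config.criterion}).to_csv(
        path, index=False
    )


def write_ground_truth(params: JudgeSimParams, path: str) -> None:
    """Sidecar JSON with the generating parameters, for recovery tests."""
    d = asdict(params)
    if d.get("beta") is not None:
        d["beta"] = list(np.asarray(d["beta"], dtype=float))
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2)
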