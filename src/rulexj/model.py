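"""The RulEx-J measurement model for continuous cues and its posterior sampler.

A participant's judgment of stimulus *s* blends two interim judgments,

    J(s) = alpha * J_R(s) + (1 - alpha) * J_E(s),

where ``J_R`` comes from a cue-abstraction (linear additive) rule,
``J_R = beta0 + sum_k beta_k c_k``, and ``J_E`` from a simplified generalized
context model with equal cue weights: exemplar similarity decays
exponentially with Euclidean cue distance, ``s_j = exp(-h * d_j)``, and the
prediction is the similarity-weighted average of the exemplars' criterion
values.  ``alpha`` in [0, 1] measures the relative contribution of rule-based
(alpha near 1) versus exemplar-based (alpha near 0) processing.

The hierarchical Bayesian version places a probit-normal population structure
on alpha: ``probit(alpha_i) = theta_i ~ Normal(mu_alpha[j], sigma_theta^2)``
for participant *i* in condition *j*, with condition means

    mu_alpha_1 = mu + delta * sigma_theta / 2
    mu_alpha_2 = mu - delta * sigma_theta / 2

so that ``delta`` is the standardized between-condition difference in alpha
(an effect size on the probit scale).  Rule weights are hierarchically normal
and the positive scales (exemplar sensitivity ``h``, response noise
``sigma``) hierarchically log-normal across participants.  Responses are
modeled as Gaussian around the mixture prediction.

Sampling uses a Metropolis-within-Gibbs scheme vectorized across chains and
participants: rule weights have a conjugate Gaussian full conditional, the
condition means a conjugate bivariate-Gaussian full conditional, and the
remaining blocks use adaptively scaled random-walk proposals (adaptation
restricted to burn-in).  Pure rule-based (alpha = 1) and pure exemplar-based
(alpha = 0) restrictions of the model are available for model comparison.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import norm

__all__ = [
    "CueMatrix",
    "ExemplarSet",
    "ParticipantParams",
    "Priors",
    "SamplerSettings",
    "RulExJPosterior",
    "rule_prediction",
    "exemplar_prediction",
    "mixture_prediction",
    "log_likelihood",
    "sample_posterior",
    "extend_posterior",
    "rhat",
    "hdi",
    "summarize_posterior",
    "write_posterior",
    "read_judgments",
    "write_judgments",
]

JUDGMENT_COLUMNS = ["participant_id", "condition", "stim_id", "is_old", "response"]


# ---------------------------------------------------------------------------
# containers


@dataclass
class CueMatrix:
    """Stimulus cue values (MDS coordinates used as continuous cues)."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels and cue rows must align")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("stimulus labels must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cue values must be finite")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass
class ExemplarSet:
    """Stored exemplars: cue vectors plus known criterion values."""

    labels: list[str]
    cue_vectors: np.ndarray
    criterion: np.ndarray

    def __post_init__(self) -> None:
        self.cue_vectors = np.atleast_2d(np.asarray(self.cue_vectors, dtype=float))
        self.criterion = np.asarray(self.criterion, dtype=float)
        if self.cue_vectors.shape[0] != self.criterion.size:
            raise ValueError("cue_vectors and criterion must align")
        if self.criterion.size < 1:
            raise ValueError("need at least one exemplar")

    @property
    def m(self) -> int:
        return self.criterion.size


@dataclass
class ParticipantParams:
    """Parameters of one participant's judgment process."""

    alpha: float
    beta0: float
    beta: np.ndarray
    h: float
    sigma_resp: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.h <= 0 or self.sigma_resp <= 0:
            raise ValueError("h and sigma_resp must be positive")


@dataclass
class Priors:
    """Prior settings for the hierarchical model.

    Scale-bearing defaults (rule-weight scales, response-noise location) are
    filled in from the response range at fit time when left as None.
    """

    mu_loc: float = 0.0
    mu_scale: float = 1.0
    delta_loc: float = 0.0
    delta_scale: float = 1.0
    sigma_theta_scale: float = 1.0  # half-normal
    mu_beta_loc: np.ndarray | None = None
    mu_beta_scale: np.ndarray | None = None
    tau_beta_scale: np.ndarray | None = None  # half-normal
    # log h is per standardized cue-distance unit; within-set distances are
    # order 1-2, so h in roughly e^(+/-2) spans flat to sharp similarity
    # gradients -- mass far below that collapses the exemplar module to a
    # constant, which the intercept absorbs
    mu_log_h_loc: float = 0.0
    mu_log_h_scale: float = 1.0
    tau_log_h_scale: float = 0.5
    mu_log_sigma_loc: float | None = None
    mu_log_sigma_scale: float = 1.5
    tau_log_sigma_scale: float = 1.0
    # non-hierarchical reductions: hold the beta prior scale or the response
    # noise fixed instead of sampling them (useful for conjugate checks and
    # deliberately simplified fits)
    fix_tau_beta: float | np.ndarray | None = None
    fix_sigma_resp: float | None = None

    def delta_prior(self) -> "norm":
        """The prior on delta as a frozen scipy distribution (the same object
        family the Savage-Dickey ratio must evaluate)."""
        return norm(self.delta_loc, self.delta_scale)


@dataclass
class SamplerSettings:
    n_chains: int = 4
    n_kept: int = 5000
    burn_in: int = 1000
    thin: int = 1
    seed: int = 0

    @property
    def n_iter(self) -> int:
        return self.burn_in + self.n_kept * self.thin


@dataclass
class RulExJPosterior:
    """MCMC output: per-parameter sample arrays with leading (chain, draw)
    axes, split-chain R-hat diagnostics, and the settings used."""

    chains: dict[str, np.ndarray]
    rhat: dict[str, float]
    settings: SamplerSettings
    participant_ids: list[str]
    conditions: list[str]
    model: str = "rulexj"
    converged: bool = True
    delta_prior: object | None = None
    _ctx: object | None = field(default=None, repr=False)
    _sampler: object | None = field(default=None, repr=False)

    def stacked(self, name: str) -> np.ndarray:
        """Samples pooled over chains (draws first axis)."""
        x = self.chains[name]
        return x.reshape(-1, *x.shape[2:])


# ---------------------------------------------------------------------------
# deterministic model components


def rule_prediction(cue_vec: np.ndarray, beta0: float, beta: np.ndarray) -> float | np.ndarray:
    """Cue-abstraction rule: intercept plus weighted linear sum of cues."""
    cue_vec = np.asarray(cue_vec, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if cue_vec.shape[-1] != beta.shape[-1]:
        raise ValueError("cue vector and beta must have matching length")
    return beta0 + cue_vec @ beta


def exemplar_prediction(
    cue_vec: np.ndarray, ex: ExemplarSet, h: float, metric: str = "euclidean"
) -> float | np.ndarray:
    """Simplified GCM prediction with equal cue weights.

    Similarity to exemplar j is ``exp(-h * d_j)``; the prediction is the
    similarity-weighted mean of exemplar criterion values.  Computed with a
    max-shift so that when every raw similarity underflows the prediction
    degrades gracefully to the nearest exemplar's criterion (a warning is
    emitted in that case).
    """
    if h <= 0:
        raise ValueError("h must be positive")
    cue_vec = np.asarray(cue_vec, dtype=float)
    single = cue_vec.ndim == 1
    probes = np.atleast_2d(cue_vec)
    diff = probes[:, None, :] - ex.cue_vectors[None, :, :]
    if metric == "euclidean":
        d = np.sqrt((diff**2).sum(-1))
    elif metric == "cityblock":
        d = np.abs(diff).sum(-1)
    else:
        raise ValueError("metric must be 'euclidean' or 'cityblock'")
    w = np.exp(-h * d)
    tot = w.sum(axis=1)
    dead = tot == 0.0
    if np.any(dead):
        warnings.warn(
            "all exemplar similarities underflow; falling back to the "
            "nearest exemplar's criterion",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        pred = (w * ex.criterion[None, :]).sum(1) / tot
    if np.any(dead):
        pred[dead] = ex.criterion[np.argmin(d[dead], axis=1)]
    return float(pred[0]) if single else pred


def mixture_prediction(alpha: float, j_r, j_e):
    """RulEx-J mixture of the rule and exemplar interim judgments."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    return alpha * np.asarray(j_r) + (1.0 - alpha) * np.asarray(j_e)


def log_likelihood(
    data: pd.DataFrame,
    cues: CueMatrix,
    ex: ExemplarSet,
    params: dict[str, ParticipantParams],
) -> float:
    """Gaussian log-likelihood of a judgment table under per-participant
    RulEx-J parameters (on the raw cue scale)."""
    index = {s: i for i, s in enumerate(cues.labels)}
    missing = set(data["stim_id"].astype(str)) - set(index)
    if missing:
        raise ValueError(f"stimuli without cues: {sorted(missing)}")
    total = 0.0
    for pid, grp in data.groupby("participant_id", sort=False):
        p = params[str(pid)]
        sidx = grp["stim_id"].astype(str).map(index).to_numpy()
        x = cues.values[sidx]
        jr = rule_prediction(x, p.beta0, p.beta)
        je = exemplar_prediction(x, ex, p.h)
        mu = mixture_prediction(p.alpha, jr, je)
        resid = grp["response"].to_numpy(float) - mu
        total += float(
            -0.5 * len(resid) * np.log(2 * np.pi * p.sigma_resp**2)
            - 0.5 * np.sum(resid**2) / p.sigma_resp**2
        )
    return total


# ---------------------------------------------------------------------------
# convergence diagnostics


def rhat(chains: np.ndarray) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws); each chain is split in half,
    giving 2C sequences.  Degenerate (zero-variance) samples return 1.0.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 chains of draws")
    half = x.shape[1] // 2
    if half < 2:
        raise ValueError("chains too short to split")
    parts = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, n = parts.shape
    means = parts.mean(axis=1)
    W = parts.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W <= 1e-300:
        # zero within-chain variance: identical constants are converged,
        # different constants are maximally non-mixing
        return 1.0 if B <= 1e-300 else float("inf")
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def hdi(samples: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest (highest-density) interval covering ``prob`` of the samples."""
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    k = max(1, int(np.floor(prob * n)))
    widths = x[k - 1 :] - x[: n - k + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k - 1])


# ---------------------------------------------------------------------------
# sampler internals


class _ModelContext:
    """Preprocessed data arrays plus the joint density, shared by the Gibbs
    sampler and by bridge sampling (which needs the same unnormalized
    posterior in the sampler's unconstrained parametrization)."""

    def __init__(
        self,
        data: pd.DataFrame,
        cues: CueMatrix,
        ex: ExemplarSet,
        priors: Priors | None,
        model: str,
        condition_order: tuple[str, str] | None,
        prior_only: bool = False,
        metric: str = "euclidean",
    ):
        if model not in ("rulexj", "rule", "exemplar"):
            raise ValueError("model must be 'rulexj', 'rule' or 'exemplar'")
        self.model = model
        self.prior_only = bool(prior_only)

        index = {s: i for i, s in enumerate(cues.labels)}
        stim = data["stim_id"].astype(str)
        missing = set(stim) - set(index)
        if missing:
            raise ValueError(f"stimuli without cues: {sorted(missing)}")
        pids = list(dict.fromkeys(data["participant_id"].astype(str)))
        pid_index = {p: i for i, p in enumerate(pids)}
        self.pids = pids
        self.P = len(pids)

        cond_by_pid = (
            data.assign(participant_id=data["participant_id"].astype(str))
            .groupby("participant_id", sort=False)["condition"]
            .agg(lambda s: s.iloc[0])
        )
        labels_present = sorted(set(data["condition"].astype(str)))
        if condition_order is None:
            condition_order = tuple(labels_present)
        else:
            condition_order = tuple(str(c) for c in condition_order)
            if sorted(condition_order) != labels_present:
                raise ValueError(
                    f"condition_order {condition_order} does not match data "
                    f"labels {labels_present}"
                )
        if len(condition_order) > 2:
            raise ValueError("at most two conditions are supported")
        self.conditions = list(condition_order)
        self.n_cond = len(self.conditions)
        cidx = {c: j for j, c in enumerate(self.conditions)}
        self.cond_p = np.array(
            [cidx[str(cond_by_pid[p])] for p in pids], dtype=int
        )

        # standardize cues for numerical stability: center per dimension but
        # rescale with a single global factor -- anisotropic (per-dimension)
        # scaling would distort the Euclidean geometry the exemplar
        # similarities are defined on
        X = cues.values
        self.cue_mean = X.mean(axis=0)
        sd = X.std(axis=0)
        scale = float(np.sqrt(np.mean(sd**2)))
        self.cue_sd = np.full(X.shape[1], scale if scale > 0 else 1.0)
        Xz = (X - self.cue_mean) / self.cue_sd
        self.d = Xz.shape[1]
        self.K = self.d + 1
        self.Xd = np.column_stack([np.ones(len(Xz)), Xz])  # (n, K)
        ez = (ex.cue_vectors - self.cue_mean) / self.cue_sd
        diff = Xz[:, None, :] - ez[None, :, :]
        if metric == "euclidean":
            self.Dex = np.sqrt((diff**2).sum(-1))  # (n, m)
        elif metric == "cityblock":
            self.Dex = np.abs(diff).sum(-1)
        else:
            raise ValueError("metric must be 'euclidean' or 'cityblock'")
        self.yex = np.asarray(ex.criterion, dtype=float)

        self.p_t = data["participant_id"].astype(str).map(pid_index).to_numpy()
        self.s_t = stim.map(index).to_numpy()
        self.y = data["response"].to_numpy(float)
        self.N = len(self.y)
        self.T_p = np.bincount(self.p_t, minlength=self.P).astype(float)

        # per-participant reduction operators
        self.M = np.zeros((self.N, self.P))
        self.M[np.arange(self.N), self.p_t] = 1.0
        Xt = self.Xd[self.s_t]  # (N, K)
        self.Mx = np.zeros((self.N, self.P * self.K))
        self.Mx[np.arange(self.N)[:, None], self.p_t[:, None] * self.K + np.arange(self.K)[None, :]] = Xt
        self.G = np.einsum("np,nk,nl->pkl", self.M, Xt, Xt)  # (P, K, K)
        self.Xtrial = np.ascontiguousarray(Xt)  # (N, K)
        self.yty_p = (self.y**2) @ self.M  # (P,)
        self.Xty_p = (self.y @ self.Mx).reshape(self.P, self.K)  # (P, K)

        # fill scale-bearing prior defaults from the response range
        pr = priors if priors is not None else Priors()
        R = float(self.y.max() - self.y.min()) if self.N else 100.0
        R = R if R > 0 else 1.0
        ybar = float(self.y.mean()) if self.N else 0.0
        if pr.mu_beta_loc is None:
            loc = np.zeros(self.K)
            loc[0] = ybar
            pr = replace(pr, mu_beta_loc=loc)
        if pr.mu_beta_scale is None:
            pr = replace(pr, mu_beta_scale=np.full(self.K, R))
        if pr.tau_beta_scale is None:
            # between-participant spread of rule weights is plausibly a
            # fraction of the weights themselves; a much wider scale lets a
            # degenerate low-alpha regime inflate tau_beta and dominate the
            # marginal likelihood through its complexity penalty
            pr = replace(pr, tau_beta_scale=np.full(self.K, R / 8))
        if pr.mu_log_sigma_loc is None:
            pr = replace(pr, mu_log_sigma_loc=float(np.log(R / 10)))
        pr = replace(
            pr,
            mu_beta_loc=np.asarray(pr.mu_beta_loc, dtype=float),
            mu_beta_scale=np.asarray(pr.mu_beta_scale, dtype=float),
            tau_beta_scale=np.asarray(pr.tau_beta_scale, dtype=float),
        )
        self.priors = pr

        self.has_alpha = model == "rulexj"
        self.has_rule = model in ("rulexj", "rule")
        self.has_ex = model in ("rulexj", "exemplar")

        # unconstrained parameter layout (participant blocks, then hypers)
        blocks: list[tuple[str, int]] = []
        if self.has_alpha:
            blocks.append(("theta", self.P))
        if self.has_rule:
            blocks.append(("beta", self.P * self.K))
        if self.has_ex:
            blocks.append(("log_h", self.P))
        blocks.append(("log_sigma", self.P))
        if self.has_alpha:
            blocks.append(("mu", 1))
            if self.n_cond == 2:
                blocks.append(("delta", 1))
            blocks.append(("log_sigma_theta", 1))
        if self.has_rule:
            blocks.append(("mu_beta", self.K))
            blocks.append(("log_tau_beta", self.K))
        if self.has_ex:
            blocks.append(("mu_log_h", 1))
            blocks.append(("log_tau_log_h", 1))
        blocks.append(("mu_log_sigma", 1))
        blocks.append(("log_tau_log_sigma", 1))
        self.layout = []
        off = 0
        for name, size in blocks:
            self.layout.append((name, off, size))
            off += size
        self.n_params = off

    # -- vectorized model pieces (leading axes arbitrary) -------------------

    def exemplar_values(self, log_h: np.ndarray) -> np.ndarray:
        """J_E per stimulus for each (..., participant); stable softmax."""
        a = -np.exp(log_h)[..., None, None] * self.Dex  # (..., P, n, m)
        a = a - a.max(axis=-1, keepdims=True)
        w = np.exp(a)
        return (w @ self.yex) / w.sum(axis=-1)

    def rule_values(self, beta: np.ndarray) -> np.ndarray:
        """J_R per stimulus for each (..., participant); beta (..., P, K)."""
        return np.einsum("nk,...pk->...pn", self.Xd, beta)

    def trial_gather(self, per_stim: np.ndarray) -> np.ndarray:
        """(..., P, n) -> (..., N) picking each trial's participant/stimulus."""
        return per_stim[..., self.p_t, self.s_t]

    def cond_means(self, mu, delta, sigma_theta):
        """Condition-level probit means from (mu, delta, sigma_theta)."""
        if self.n_cond == 1:
            return np.stack([mu], axis=-1)
        return np.stack(
            [mu + delta * sigma_theta / 2.0, mu - delta * sigma_theta / 2.0], axis=-1
        )

    # -- joint density in the unconstrained parametrization -----------------

    def unpack(self, V: np.ndarray) -> dict[str, np.ndarray]:
        V = np.atleast_2d(V)
        out = {}
        for name, off, size in self.layout:
            x = V[:, off : off + size]
            if name == "beta":
                x = x.reshape(V.shape[0], self.P, self.K)
            elif size == 1:
                x = x[:, 0]
            out[name] = x
        return out

    def log_posterior(self, V: np.ndarray, batch: int = 256) -> np.ndarray:
        """Unnormalized log posterior density at rows of ``V`` (in the
        unconstrained space; includes log-Jacobians of the log transforms)."""
        V = np.atleast_2d(np.asarray(V, dtype=float))
        out = np.empty(V.shape[0])
        for lo in range(0, V.shape[0], batch):
            out[lo : lo + batch] = self._log_posterior_batch(V[lo : lo + batch])
        return out

    def _log_posterior_batch(self, V: np.ndarray) -> np.ndarray:
        pr = self.priors
        p = self.unpack(V)
        S = V.shape[0]
        lp = np.zeros(S)

        log_sigma = p["log_sigma"]  # (S, P)
        sig2 = np.exp(2 * log_sigma)

        # likelihood
        if not self.prior_only:
            if self.has_rule:
                jr_t = self.trial_gather(self.rule_values(p["beta"]))
            if self.has_ex:
                je_t = self.trial_gather(self.exemplar_values(p["log_h"]))
            if self.model == "rulexj":
                alpha_t = ndtr(p["theta"])[:, self.p_t]
                mix = alpha_t * jr_t + (1 - alpha_t) * je_t
            elif self.model == "rule":
                mix = jr_t
            else:
                mix = je_t
            resid2 = (self.y[None, :] - mix) ** 2
            ssr = resid2 @ self.M  # (S, P)
            lp += (
                -0.5 * ssr / sig2
                - self.T_p[None, :] * (log_sigma + 0.5 * np.log(2 * np.pi))
            ).sum(axis=1)

        # participant-level priors
        if self.has_alpha:
            sigma_theta = np.exp(p["log_sigma_theta"])
            delta = p.get("delta", np.zeros(S))
            mcond = self.cond_means(p["mu"], delta, sigma_theta)  # (S, n_cond)
            mtheta = mcond[:, self.cond_p] if self.n_cond > 1 else mcond[:, [0] * self.P]
            lp += _norm_logpdf(p["theta"], mtheta, sigma_theta[:, None]).sum(axis=1)
        if self.has_rule:
            lp += _norm_logpdf(
                p["beta"],
                p["mu_beta"][:, None, :],
                np.exp(p["log_tau_beta"])[:, None, :],
            ).sum(axis=(1, 2))
        if self.has_ex:
            lp += _norm_logpdf(
                p["log_h"], p["mu_log_h"][:, None], np.exp(p["log_tau_log_h"])[:, None]
            ).sum(axis=1)
        lp += _norm_logpdf(
            log_sigma, p["mu_log_sigma"][:, None], np.exp(p["log_tau_log_sigma"])[:, None]
        ).sum(axis=1)

        # hyperpriors (with log-Jacobians for log-transformed scales)
        if self.has_alpha:
            lp += _norm_logpdf(p["mu"], pr.mu_loc, pr.mu_scale)
            if self.n_cond == 2:
                lp += _norm_logpdf(p["delta"], pr.delta_loc, pr.delta_scale)
            lp += _halfnorm_logpdf(sigma_theta, pr.sigma_theta_scale) + p["log_sigma_theta"]
        if self.has_rule:
            lp += _norm_logpdf(
                p["mu_beta"], pr.mu_beta_loc[None, :], pr.mu_beta_scale[None, :]
            ).sum(axis=1)
            tau_b = np.exp(p["log_tau_beta"])
            lp += (
                _halfnorm_logpdf(tau_b, pr.tau_beta_scale[None, :]) + p["log_tau_beta"]
            ).sum(axis=1)
        if self.has_ex:
            lp += _norm_logpdf(p["mu_log_h"], pr.mu_log_h_loc, pr.mu_log_h_scale)
            tau_h = np.exp(p["log_tau_log_h"])
            lp += _halfnorm_logpdf(tau_h, pr.tau_log_h_scale) + p["log_tau_log_h"]
        lp += _norm_logpdf(p["mu_log_sigma"], pr.mu_log_sigma_loc, pr.mu_log_sigma_scale)
        tau_s = np.exp(p["log_tau_log_sigma"])
        lp += _halfnorm_logpdf(tau_s, pr.tau_log_sigma_scale) + p["log_tau_log_sigma"]
        return lp


def _norm_logpdf(x, loc, scale):
    z = (np.asarray(x) - loc) / scale
    return -0.5 * z**2 - np.log(scale) - 0.5 * np.log(2 * np.pi)


# JIT fast paths for the two sampler hot spots (pure-numpy fallbacks below)
try:
    from numba import njit as _njit

    @_njit(cache=True, fastmath=True)
    def _je_kernel(h, Dex, yex):  # h (C, P) -> (C, P, n)
        C, P = h.shape
        n, m = Dex.shape
        out = np.empty((C, P, n))
        for c in range(C):
            for p in range(P):
                hh = h[c, p]
                for i in range(n):
                    amax = -1e300
                    for j in range(m):
                        a = -hh * Dex[i, j]
                        if a > amax:
                            amax = a
                    num = 0.0
                    den = 0.0
                    for j in range(m):
                        w = np.exp(-hh * Dex[i, j] - amax)
                        num += w * yex[j]
                        den += w
                    out[c, p, i] = num / den
        return out

    @_njit(cache=True, fastmath=True)
    def _ssr_kernel(alpha, p_t, jr_t, je_t, y, P):  # -> (C, P)
        C, N = jr_t.shape
        ssr = np.zeros((C, P))
        for c in range(C):
            for t in range(N):
                p = p_t[t]
                a = alpha[c, p]
                r = y[t] - (a * jr_t[c, t] + (1.0 - a) * je_t[c, t])
                ssr[c, p] += r * r
        return ssr

    @_njit(cache=True, fastmath=True)
    def _je_stats_kernel(je_t, y, Xt, p_t, P):
        """Scatter-reduce the per-participant exemplar-prediction stats:
        ye = sum_t y_t JE_t, ee = sum_t JE_t^2, XtJE = sum_t x_t JE_t."""
        C, N = je_t.shape
        K = Xt.shape[1]
        ye = np.zeros((C, P))
        ee = np.zeros((C, P))
        XtJE = np.zeros((C, P, K))
        for c in range(C):
            for t in range(N):
                p = p_t[t]
                e = je_t[c, t]
                ye[c, p] += y[t] * e
                ee[c, p] += e * e
                for k in range(K):
                    XtJE[c, p, k] += Xt[t, k] * e
        return ye, ee, XtJE

    @_njit(cache=True, fastmath=True)
    def _marginal_kernel(a, sig2, tau, mu_b, ye, ee, XtJE, G, Xty, yty, T_p):
        """Beta-marginalized Gaussian log-likelihood per (chain, participant);
        see _GibbsSampler._marginal_rule_ll for the algebra."""
        C, P = a.shape
        K = tau.shape[1]
        out = np.empty((C, P))
        v = np.empty(K)
        L = np.empty((K, K))
        z = np.empty(K)
        Gmu = np.empty(K)
        for c in range(C):
            for p in range(P):
                ap = a[c, p]
                om = 1.0 - ap
                s2 = sig2[c, p]
                ytf = 0.0
                etf = 0.0
                ftf = 0.0
                for k in range(K):
                    g = 0.0
                    for l in range(K):
                        g += G[p, k, l] * mu_b[c, l]
                    Gmu[k] = g
                    ytf += Xty[p, k] * mu_b[c, k]
                    etf += XtJE[c, p, k] * mu_b[c, k]
                    ftf += mu_b[c, k] * g
                rtr = (
                    yty[p]
                    - 2.0 * om * ye[c, p]
                    - 2.0 * ap * ytf
                    + om * om * ee[c, p]
                    + 2.0 * ap * om * etf
                    + ap * ap * ftf
                )
                for k in range(K):
                    v[k] = tau[c, k] * (Xty[p, k] - om * XtJE[c, p, k] - ap * Gmu[k])
                ratio = ap * ap / s2
                # L = chol(I + ratio * T G T)
                for k in range(K):
                    for l in range(k + 1):
                        acc = ratio * tau[c, k] * G[p, k, l] * tau[c, l]
                        if k == l:
                            acc += 1.0
                        for m in range(l):
                            acc -= L[k, m] * L[l, m]
                        if k == l:
                            L[k, k] = np.sqrt(acc)
                        else:
                            L[k, l] = acc / L[l, l]
                logdet = 0.0
                for k in range(K):
                    logdet += 2.0 * np.log(L[k, k])
                # solve L z = v ; quad = z.z (v' M^-1 v = ||L^-1 v||^2)
                for k in range(K):
                    acc = v[k]
                    for m in range(k):
                        acc -= L[k, m] * z[m]
                    z[k] = acc / L[k, k]
                quad = 0.0
                for k in range(K):
                    quad += z[k] * z[k]
                rSr = (rtr - ratio * quad) / s2
                out[c, p] = -0.5 * (
                    T_p[p] * np.log(2.0 * np.pi * s2) + logdet + rSr
                )
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False
    _marginal_kernel = None
    _je_stats_kernel = None

    def _je_kernel(h, Dex, yex):
        a = -h[..., None, None] * Dex
        a = a - a.max(axis=-1, keepdims=True)
        w = np.exp(a)
        return (w @ yex) / w.sum(axis=-1)

    def _ssr_kernel(alpha, p_t, jr_t, je_t, y, P):
        a_t = alpha[:, p_t]
        resid = y[None, :] - (a_t * jr_t + (1.0 - a_t) * je_t)
        M = np.zeros((y.size, P))
        M[np.arange(y.size), p_t] = 1.0
        return (resid**2) @ M


def _halfnorm_logpdf(x, scale):
    return np.where(
        np.asarray(x) > 0,
        0.5 * np.log(2 / np.pi) - np.log(scale) - 0.5 * (np.asarray(x) / scale) ** 2,
        -np.inf,
    )


_LOG_H_BOUND = 10.0  # support bound on log h (numerical guard; h in e^(+/-10))
_LOG_SIG_BOUND = 15.0  # support bound on log sigma (numerical guard)


class _GibbsSampler:
    """Metropolis-within-Gibbs, vectorized over (chains, participants)."""

    TARGET = 0.44  # scalar random-walk acceptance target

    def __init__(self, ctx: _ModelContext, settings: SamplerSettings):
        self.ctx = ctx
        self.st = settings
        self.rng = np.random.default_rng(settings.seed)
        C, P, K = settings.n_chains, ctx.P, ctx.K
        self.C, self.P, self.K = C, P, K
        pr = ctx.priors
        rng = self.rng
        lik = 0.0 if ctx.prior_only else 1.0
        self.lik = lik

        # initial state: per-participant ridge fits plus chain jitter
        y, M, T = ctx.y, ctx.M, np.maximum(ctx.T_p, 1.0)
        ybar_p = (y @ M) / T
        self.theta = 0.3 * rng.standard_normal((C, P))
        b0 = np.zeros((P, K))
        if ctx.has_rule and not ctx.prior_only and ctx.N:
            for p in range(P):
                sel = ctx.p_t == p
                Xp = ctx.Xd[ctx.s_t[sel]]
                A = Xp.T @ Xp + 1e-3 * np.eye(K)
                b0[p] = np.linalg.solve(A, Xp.T @ y[sel])
        else:
            b0[:, 0] = ybar_p
        self.beta = b0[None] + 0.1 * (np.abs(b0[None]) + 1.0) * rng.standard_normal((C, P, K))
        self.log_h = 0.3 * rng.standard_normal((C, P))
        if ctx.N and not ctx.prior_only:
            resid0 = y - ybar_p[ctx.p_t]
            s0 = np.sqrt(max(((resid0**2) @ M / T).mean(), 1e-2))
        else:
            s0 = np.exp(pr.mu_log_sigma_loc)
        self.log_sigma = np.log(s0) + 0.2 * rng.standard_normal((C, P))

        self.mu = 0.2 * rng.standard_normal(C)
        self.delta = 0.2 * rng.standard_normal(C)
        self.log_sigma_theta = np.log(0.5) + 0.2 * rng.standard_normal(C)
        self.mu_beta = self.beta.mean(axis=1)
        self.log_tau_beta = np.log(self.beta.std(axis=1) + 0.5)
        if pr.fix_tau_beta is not None:
            self.log_tau_beta = np.broadcast_to(
                np.log(np.asarray(pr.fix_tau_beta, dtype=float)), (C, K)
            ).copy()
        if pr.fix_sigma_resp is not None:
            self.log_sigma = np.full((C, P), np.log(pr.fix_sigma_resp))
        self.mu_log_h = self.log_h.mean(axis=1)
        self.log_tau_log_h = np.full(C, np.log(0.5))
        self.mu_log_sigma = self.log_sigma.mean(axis=1)
        self.log_tau_log_sigma = np.full(C, np.log(0.5))

        # random-walk step sizes (adapted during burn-in only)
        self.step = {
            "theta": np.full((C, P), 0.4),
            "log_h": np.full((C, P), 0.4),
            "log_sigma": np.full((C, P), 0.3),
            "log_sigma_theta": np.full(C, 0.3),
            "sigma_theta_nc": np.full(C, 0.5),
            "theta_shift": np.full(C, 0.3),
            "theta_diff": np.full(C, 0.5),
            "h_shift": np.full(C, 0.2),
            "h_scale": np.full(C, 0.5),
            "ls_shift": np.full(C, 0.1),
            "ls_scale": np.full(C, 0.5),
            "joint_level": np.full(C, 1.0),
            "tau_beta": np.full((C, K), 0.3),
            "tau_log_h": np.full(C, 0.3),
            "tau_log_sigma": np.full(C, 0.3),
        }
        self._acc = {k: np.zeros_like(v) for k, v in self.step.items()}
        self._try = 0

        # adaptive proposal for the joint group-level translation
        jd = K + 2
        self._joint_mean = np.concatenate(
            [self.mu[:, None], self.mu_log_h[:, None], self.mu_beta], axis=1
        )
        scale0 = np.concatenate([[0.1, 0.1], 0.05 * (np.abs(self.mu_beta.mean(0)) + 1.0)])
        self._joint_cov = np.tile(np.diag(scale0**2), (C, 1, 1))
        self._joint_chol = np.linalg.cholesky(self._joint_cov + 1e-6 * np.eye(jd))

        self.alpha = ndtr(self.theta)
        self._refresh_caches()

    # -- cache handling ------------------------------------------------------

    def _alpha_eff(self) -> np.ndarray:
        if self.ctx.model == "rulexj":
            return self.alpha
        const = 1.0 if self.ctx.model == "rule" else 0.0
        return np.full((self.C, self.P), const)

    def _refresh_caches(self):
        ctx = self.ctx
        if ctx.has_rule:
            self.JR_t = np.ascontiguousarray(
                ctx.trial_gather(ctx.rule_values(self.beta))
            )
        if ctx.has_ex:
            self.JE = _je_kernel(np.exp(self.log_h), ctx.Dex, ctx.yex)
            self.JE_t = np.ascontiguousarray(ctx.trial_gather(self.JE))
        if ctx.has_rule and ctx.has_ex:
            self._stats = self._je_stats(self.JE_t)
        if not ctx.has_ex:
            self.JE_t = self.JR_t
        if not ctx.has_rule:
            self.JR_t = self.JE_t
        self._recompute_ssr()

    def _recompute_ssr(self):
        ctx = self.ctx
        self.ssr = _ssr_kernel(
            self._alpha_eff(), ctx.p_t, self.JR_t, self.JE_t, ctx.y, self.P
        )

    def _mh_accept(self, name, log_ratio, shape):
        acc = np.log(self.rng.random(shape)) < log_ratio
        self._acc[name] += acc
        return acc

    def _adapt(self, window):
        for k, s in self.step.items():
            rate = self._acc[k] / window
            self.step[k] = np.clip(s * np.exp(1.5 * (rate - self.TARGET)), 1e-3, 10.0)
            self._acc[k][...] = 0.0

    # -- parameter blocks ----------------------------------------------------

    def _je_stats(self, je_t: np.ndarray) -> tuple:
        """Per-participant reductions of the exemplar predictions needed by
        the beta-marginalized likelihood."""
        ctx = self.ctx
        if _je_stats_kernel is not None:
            return _je_stats_kernel(je_t, ctx.y, ctx.Xtrial, ctx.p_t, self.P)
        ye = (ctx.y[None] * je_t) @ ctx.M
        ee = (je_t**2) @ ctx.M
        XtJE = (je_t @ ctx.Mx).reshape(self.C, self.P, self.K)
        return ye, ee, XtJE

    def _marginal_rule_ll(
        self,
        a: np.ndarray,
        je_stats: tuple,
        mu_b: np.ndarray | None = None,
        log_tau_b: np.ndarray | None = None,
    ) -> np.ndarray:
        """Per-participant log-likelihood at mixture weight ``a`` with the
        rule weights beta_i integrated out under their (Gaussian) hierarchy:

            y | a, h, sigma ~ N(a X mu_b + (1-a) J_E,
                                sigma^2 I + a^2 X diag(tau_b^2) X^T),

        evaluated via the Woodbury identity and the matrix determinant lemma
        so only K x K solves are needed.  Collapsing beta removes the tight
        posterior coupling between alpha and the rule weights that otherwise
        stalls a fixed-beta random walk on theta."""
        ctx = self.ctx
        C, P, K = self.C, self.P, self.K
        sig2 = np.exp(2 * self.log_sigma)  # (C, P)
        tau = np.exp(log_tau_b if log_tau_b is not None else self.log_tau_beta)
        mu_b = mu_b if mu_b is not None else self.mu_beta  # (C, K)

        ye, ee, XtJE = je_stats
        if _marginal_kernel is not None:
            return _marginal_kernel(
                np.ascontiguousarray(a), sig2, tau, mu_b, ye, ee, XtJE,
                ctx.G, ctx.Xty_p, ctx.yty_p, ctx.T_p,
            )
        Gmu = np.einsum("pkl,cl->cpk", ctx.G, mu_b)  # (C, P, K)
        ytf = np.einsum("pk,ck->cp", ctx.Xty_p, mu_b)
        etf = np.einsum("cpk,ck->cp", XtJE, mu_b)
        ftf = np.einsum("ck,cpk->cp", mu_b, Gmu)

        one_m = 1.0 - a
        rtr = (
            ctx.yty_p[None]
            - 2 * one_m * ye
            - 2 * a * ytf
            + one_m**2 * ee
            + 2 * a * one_m * etf
            + a**2 * ftf
        )
        Xtr = (
            ctx.Xty_p[None]
            - one_m[..., None] * XtJE
            - a[..., None] * Gmu
        )
        v = tau[:, None, :] * Xtr  # (C, P, K)
        W = tau[:, None, :, None] * ctx.G[None] * tau[:, None, None, :]
        ratio = (a**2 / sig2)[..., None, None]
        Mmat = np.eye(K)[None, None] + ratio * W
        L = np.linalg.cholesky(Mmat)
        logdet = 2.0 * np.log(np.diagonal(L, axis1=-2, axis2=-1)).sum(-1)
        z = np.linalg.solve(Mmat, v[..., None])[..., 0]
        quad = (v * z).sum(-1)
        rSr = (rtr - (a**2 / sig2) * quad) / sig2
        return -0.5 * (ctx.T_p[None] * np.log(2 * np.pi * sig2) + logdet + rSr)

    def _update_theta(self):
        """Collapsed Metropolis step on theta (beta integrated out); beta is
        redrawn from its full conditional immediately afterwards."""
        ctx = self.ctx
        prop = self.theta + self.step["theta"] * self.rng.standard_normal((self.C, self.P))
        a_prop = ndtr(prop)
        if self.lik:
            dll = self._marginal_rule_ll(a_prop, self._stats) - self._marginal_rule_ll(
                self.alpha, self._stats
            )
        else:
            dll = np.zeros((self.C, self.P))
        st = np.exp(self.log_sigma_theta)[:, None]
        mcond = ctx.cond_means(self.mu, self.delta if ctx.n_cond == 2 else 0.0, st[:, 0])
        m = mcond[:, ctx.cond_p]
        dlp = (-((prop - m) ** 2) + (self.theta - m) ** 2) / (2 * st**2)
        acc = self._mh_accept("theta", dll + dlp, (self.C, self.P))
        self.theta = np.where(acc, prop, self.theta)
        self.alpha = np.where(acc, a_prop, self.alpha)

    def _update_beta(self):
        ctx = self.ctx
        C, P, K = self.C, self.P, self.K
        alpha = self.alpha if ctx.model == "rulexj" else np.ones((C, P))
        sig2 = np.exp(2 * self.log_sigma)
        if ctx.model == "rulexj":
            r = ctx.y[None] - (1 - alpha[:, ctx.p_t]) * self.JE_t
        else:
            r = np.broadcast_to(ctx.y[None], (C, ctx.N)).copy()
        S = (r @ ctx.Mx).reshape(C, P, K)
        tau2 = np.exp(2 * self.log_tau_beta)  # (C, K)
        prec_prior = 1.0 / tau2
        Prec = self.lik * (alpha**2 / sig2)[..., None, None] * ctx.G[None] + (
            prec_prior[:, None, :, None] * np.eye(K)[None, None]
        )
        rhs = self.lik * (alpha / sig2)[..., None] * S + (self.mu_beta / tau2)[:, None, :]
        Cov = np.linalg.inv(Prec)
        mean = np.einsum("cpkl,cpl->cpk", Cov, rhs)
        L = np.linalg.cholesky(Cov)
        z = self.rng.standard_normal((C, P, K))
        self.beta = mean + np.einsum("cpkl,cpl->cpk", L, z)
        self.JR_t = np.ascontiguousarray(ctx.trial_gather(ctx.rule_values(self.beta)))
        if not ctx.has_ex:
            self.JE_t = self.JR_t
        self._recompute_ssr()

    def _update_log_h(self):
        ctx = self.ctx
        prop = self.log_h + self.step["log_h"] * self.rng.standard_normal((self.C, self.P))
        oob = np.abs(prop) > _LOG_H_BOUND
        JE_prop = _je_kernel(np.exp(np.clip(prop, -_LOG_H_BOUND, _LOG_H_BOUND)), ctx.Dex, ctx.yex)
        JE_t_prop = np.ascontiguousarray(ctx.trial_gather(JE_prop))
        if ctx.has_rule:
            # beta-marginalized acceptance (same collapsing as the theta
            # block; h and the rule weights are tightly coupled otherwise)
            if self.lik:
                a = self._alpha_eff()
                stats_prop = self._je_stats(JE_t_prop)
                dll = self._marginal_rule_ll(a, stats_prop) - self._marginal_rule_ll(
                    a, self._stats
                )
            else:
                stats_prop = self._stats
                dll = np.zeros((self.C, self.P))
            ssr_new = None
        else:
            ssr_new = _ssr_kernel(
                self._alpha_eff(), ctx.p_t, JE_t_prop, JE_t_prop, ctx.y, self.P
            )
            sig2 = np.exp(2 * self.log_sigma)
            dll = self.lik * -(ssr_new - self.ssr) / (2 * sig2)
        tau = np.exp(self.log_tau_log_h)[:, None]
        mu = self.mu_log_h[:, None]
        dlp = (-((prop - mu) ** 2) + (self.log_h - mu) ** 2) / (2 * tau**2)
        dlp = np.where(oob, -np.inf, dlp)  # hard support bound on log h
        acc = self._mh_accept("log_h", dll + dlp, (self.C, self.P))
        self.log_h = np.where(acc, prop, self.log_h)
        self.JE = np.where(acc[..., None], JE_prop, self.JE)
        self.JE_t = np.ascontiguousarray(np.where(acc[:, ctx.p_t], JE_t_prop, self.JE_t))
        if ctx.has_rule:
            if self.lik:
                # the stats are per participant, so merge them by acceptance
                self._stats = tuple(
                    np.where(acc if cur.ndim == 2 else acc[..., None], new, cur)
                    for cur, new in zip(self._stats, stats_prop)
                )
        else:
            self.JR_t = self.JE_t
            self.ssr = np.where(acc, ssr_new, self.ssr)

    def _update_log_sigma(self):
        ctx = self.ctx
        if ctx.priors.fix_sigma_resp is not None:
            return
        prop = self.log_sigma + self.step["log_sigma"] * self.rng.standard_normal(
            (self.C, self.P)
        )
        safe = np.clip(prop, -_LOG_SIG_BOUND, _LOG_SIG_BOUND)
        dll = self.lik * (
            -ctx.T_p[None] * (safe - self.log_sigma)
            - 0.5 * self.ssr * (np.exp(-2 * safe) - np.exp(-2 * self.log_sigma))
        )
        tau = np.exp(self.log_tau_log_sigma)[:, None]
        mu = self.mu_log_sigma[:, None]
        dlp = (-((prop - mu) ** 2) + (self.log_sigma - mu) ** 2) / (2 * tau**2)
        dlp = np.where(np.abs(prop) > _LOG_SIG_BOUND, -np.inf, dlp)
        acc = self._mh_accept("log_sigma", dll + dlp, (self.C, self.P))
        self.log_sigma = np.where(acc, prop, self.log_sigma)

    def _update_theta_hypers(self):
        ctx, pr = self.ctx, self.ctx.priors
        C = self.C
        st = np.exp(self.log_sigma_theta)
        # conjugate draw of the condition means given sigma_theta
        if ctx.n_cond == 2:
            n_j = np.array(
                [np.sum(ctx.cond_p == 0), np.sum(ctx.cond_p == 1)], dtype=float
            )
            sums = np.stack(
                [
                    self.theta[:, ctx.cond_p == 0].sum(axis=1),
                    self.theta[:, ctx.cond_p == 1].sum(axis=1),
                ],
                axis=1,
            )  # (C, 2)
            q = st**2 * pr.delta_scale**2 / 4.0
            s2mu = pr.mu_scale**2
            Sig0 = np.empty((C, 2, 2))
            Sig0[:, 0, 0] = Sig0[:, 1, 1] = s2mu + q
            Sig0[:, 0, 1] = Sig0[:, 1, 0] = s2mu - q
            mu0 = np.array([pr.mu_loc + 0.0, pr.mu_loc + 0.0])
            prior_mean_shift = pr.delta_loc * st[:, None] / 2.0 * np.array([1.0, -1.0])
            mu0_full = mu0[None, :] + prior_mean_shift
            Prec = np.linalg.inv(Sig0)
            Prec[:, 0, 0] += n_j[0] / st**2
            Prec[:, 1, 1] += n_j[1] / st**2
            rhs = np.einsum("cij,cj->ci", np.linalg.inv(Sig0), mu0_full) + sums / st[:, None] ** 2
            Cov = np.linalg.inv(Prec)
            mean = np.einsum("cij,cj->ci", Cov, rhs)
            L = np.linalg.cholesky(Cov)
            m = mean + np.einsum("cij,cj->ci", L, self.rng.standard_normal((C, 2)))
            self.mu = (m[:, 0] + m[:, 1]) / 2.0
            self.delta = (m[:, 0] - m[:, 1]) / st
        else:
            n = float(self.P)
            prec = 1.0 / pr.mu_scale**2 + n / st**2
            mean = (pr.mu_loc / pr.mu_scale**2 + self.theta.sum(axis=1) / st**2) / prec
            self.mu = mean + self.rng.standard_normal(C) / np.sqrt(prec)

        # random walk on log sigma_theta with (mu, delta) held fixed
        prop = self.log_sigma_theta + self.step["log_sigma_theta"] * self.rng.standard_normal(C)
        delta = self.delta if ctx.n_cond == 2 else np.zeros(C)

        def theta_ll(log_st):
            s = np.exp(log_st)
            mcond = ctx.cond_means(self.mu, delta, s)
            m = mcond[:, ctx.cond_p]
            ll = (
                -self.P * log_st
                - ((self.theta - m) ** 2).sum(axis=1) / (2 * s**2)
            )
            return ll + _halfnorm_logpdf(s, pr.sigma_theta_scale) + log_st

        log_ratio = theta_ll(prop) - theta_ll(self.log_sigma_theta)
        acc = self._mh_accept("log_sigma_theta", log_ratio, (C,))
        self.log_sigma_theta = np.where(acc, prop, self.log_sigma_theta)

    def _update_theta_interweave(self):
        """Collapsed joint moves on (mu, delta, sigma_theta) together with
        all theta, with beta marginalized out.

        When sigma_theta is small the per-participant random walk cannot
        relocate the theta cluster (every theta is glued to its condition
        mean), so three whole-cluster moves are interleaved: a global
        translation (mu and all theta), a differential translation (delta
        and the condition-signed theta), and a non-centered rescale
        (sigma_theta with the deviations theta - m).  Each is a
        Metropolis-Hastings move whose acceptance leaves the hierarchy's
        prior terms exactly cancelled, so only the marginal likelihood and
        the hyperprior enter."""
        ctx, pr = self.ctx, self.ctx.priors
        C = self.C

        def mll(alpha):
            if not self.lik:
                return np.zeros((C, self.P))
            return self._marginal_rule_ll(alpha, self._stats)

        mll_cur = mll(self.alpha)

        # global translation: mu' = mu + eps, theta' = theta + eps
        eps = self.step["theta_shift"] * self.rng.standard_normal(C)
        theta_p = self.theta + eps[:, None]
        a_p = ndtr(theta_p)
        mll_p = mll(a_p)
        dlp = _norm_logpdf(self.mu + eps, pr.mu_loc, pr.mu_scale) - _norm_logpdf(
            self.mu, pr.mu_loc, pr.mu_scale
        )
        acc = self._mh_accept(
            "theta_shift", (mll_p - mll_cur).sum(axis=1) + dlp, (C,)
        )
        self.theta = np.where(acc[:, None], theta_p, self.theta)
        self.alpha = np.where(acc[:, None], a_p, self.alpha)
        self.mu = np.where(acc, self.mu + eps, self.mu)
        mll_cur = np.where(acc[:, None], mll_p, mll_cur)

        st = np.exp(self.log_sigma_theta)
        sign = np.where(ctx.cond_p == 0, 1.0, -1.0)[None, :]

        # differential translation: delta' = delta + eps, theta shifted by
        # +/- eps * sigma_theta / 2 according to condition
        if ctx.n_cond == 2:
            eps = self.step["theta_diff"] * self.rng.standard_normal(C)
            theta_p = self.theta + (eps * st)[:, None] / 2.0 * sign
            a_p = ndtr(theta_p)
            mll_p = mll(a_p)
            dlp = _norm_logpdf(
                self.delta + eps, pr.delta_loc, pr.delta_scale
            ) - _norm_logpdf(self.delta, pr.delta_loc, pr.delta_scale)
            acc = self._mh_accept(
                "theta_diff", (mll_p - mll_cur).sum(axis=1) + dlp, (C,)
            )
            self.theta = np.where(acc[:, None], theta_p, self.theta)
            self.alpha = np.where(acc[:, None], a_p, self.alpha)
            self.delta = np.where(acc, self.delta + eps, self.delta)
            mll_cur = np.where(acc[:, None], mll_p, mll_cur)

        # non-centered rescale of sigma_theta with the theta deviations
        delta = self.delta if ctx.n_cond == 2 else np.zeros(C)
        eps = self.step["sigma_theta_nc"] * self.rng.standard_normal(C)
        prop = self.log_sigma_theta + eps
        s_old = np.exp(self.log_sigma_theta)
        s_new = np.exp(prop)
        m_old = ctx.cond_means(self.mu, delta, s_old)[:, ctx.cond_p]
        m_new = ctx.cond_means(self.mu, delta, s_new)[:, ctx.cond_p]
        theta_p = m_new + (self.theta - m_old) * (s_new / s_old)[:, None]
        a_p = ndtr(theta_p)
        mll_p = mll(a_p)
        dlp = (
            _halfnorm_logpdf(s_new, pr.sigma_theta_scale)
            - _halfnorm_logpdf(s_old, pr.sigma_theta_scale)
            + eps
        )
        acc = self._mh_accept(
            "sigma_theta_nc", (mll_p - mll_cur).sum(axis=1) + dlp, (C,)
        )
        self.log_sigma_theta = np.where(acc, prop, self.log_sigma_theta)
        self.theta = np.where(acc[:, None], theta_p, self.theta)
        self.alpha = np.where(acc[:, None], a_p, self.alpha)

    def _update_h_cluster(self):
        """Non-centered translation and rescale of the log h hierarchy.

        When every participant has a similar sensitivity the group scale
        tau_log_h collapses and glues the individual log h to their mean;
        whole-cluster moves keep the pair (mu_log_h, {log h_i}) mobile.
        Uses the beta-marginalized likelihood when a rule module is present
        (h and the rule weights are coupled through the mixture)."""
        ctx, pr = self.ctx, self.ctx.priors
        C = self.C

        def h_dll(JE_t_prop, stats_out):
            if not self.lik:
                stats_out.append(None)
                return np.zeros(C), None
            if ctx.has_rule:
                stats_prop = self._je_stats(JE_t_prop)
                stats_out.append(stats_prop)
                a = self._alpha_eff()
                per = self._marginal_rule_ll(a, stats_prop) - self._marginal_rule_ll(
                    a, self._stats
                )
                return per.sum(axis=1), None
            stats_out.append(None)
            ssr_new = _ssr_kernel(
                self._alpha_eff(), ctx.p_t, JE_t_prop, JE_t_prop, ctx.y, self.P
            )
            sig2 = np.exp(2 * self.log_sigma)
            return (-(ssr_new - self.ssr) / (2 * sig2)).sum(axis=1), ssr_new

        # the adaptive joint move already translates the h level; the scale
        # (funnel) direction is what needs dedicated treatment, twice per
        # sweep with independently adapted steps
        for step_name in ("h_scale", "h_shift"):
            eps = self.step[step_name] * self.rng.standard_normal(C)
            mu_new = self.mu_log_h
            t_old = np.exp(self.log_tau_log_h)
            tau_new = self.log_tau_log_h + eps
            prop = self.mu_log_h[:, None] + (
                self.log_h - self.mu_log_h[:, None]
            ) * np.exp(eps)[:, None]
            dlp = (
                _halfnorm_logpdf(np.exp(tau_new), pr.tau_log_h_scale)
                - _halfnorm_logpdf(t_old, pr.tau_log_h_scale)
                + eps
            )
            dlp = np.where(
                np.abs(prop).max(axis=1) > _LOG_H_BOUND, -np.inf, dlp
            )
            JE_prop = _je_kernel(
                np.exp(np.clip(prop, -_LOG_H_BOUND, _LOG_H_BOUND)), ctx.Dex, ctx.yex
            )
            JE_t_prop = np.ascontiguousarray(ctx.trial_gather(JE_prop))
            stats_out: list = []
            dll, ssr_new = h_dll(JE_t_prop, stats_out)
            acc = self._mh_accept(step_name, dll + dlp, (C,))
            a2 = acc[:, None]
            self.log_h = np.where(a2, prop, self.log_h)
            self.mu_log_h = np.where(acc, mu_new, self.mu_log_h)
            if tau_new is not None:
                self.log_tau_log_h = np.where(acc, tau_new, self.log_tau_log_h)
            self.JE = np.where(acc[:, None, None], JE_prop, self.JE)
            self.JE_t = np.ascontiguousarray(np.where(a2, JE_t_prop, self.JE_t))
            if ctx.has_rule and self.lik:
                self._stats = tuple(
                    np.where(a2 if cur.ndim == 2 else acc[:, None, None], new, cur)
                    for cur, new in zip(self._stats, stats_out[0])
                )
            if not ctx.has_rule:
                self.JR_t = self.JE_t
                if ssr_new is not None:
                    self.ssr = np.where(a2, ssr_new, self.ssr)

    def _update_ls_cluster(self):
        """Non-centered translation and rescale of the log sigma hierarchy
        (same cluster-freeze remedy as for log h; cheap, ssr-based)."""
        ctx, pr = self.ctx, self.ctx.priors
        if ctx.priors.fix_sigma_resp is not None:
            return
        C = self.C
        for move, step_name in (("shift", "ls_shift"), ("scale", "ls_scale")):
            eps = self.step[step_name] * self.rng.standard_normal(C)
            if move == "shift":
                prop = self.log_sigma + eps[:, None]
                mu_new = self.mu_log_sigma + eps
                dlp = _norm_logpdf(
                    mu_new, pr.mu_log_sigma_loc, pr.mu_log_sigma_scale
                ) - _norm_logpdf(
                    self.mu_log_sigma, pr.mu_log_sigma_loc, pr.mu_log_sigma_scale
                )
                tau_new = None
            else:
                mu_new = self.mu_log_sigma
                t_old = np.exp(self.log_tau_log_sigma)
                tau_new = self.log_tau_log_sigma + eps
                prop = self.mu_log_sigma[:, None] + (
                    self.log_sigma - self.mu_log_sigma[:, None]
                ) * np.exp(eps)[:, None]
                dlp = (
                    _halfnorm_logpdf(np.exp(tau_new), pr.tau_log_sigma_scale)
                    - _halfnorm_logpdf(t_old, pr.tau_log_sigma_scale)
                    + eps
                )
            safe = np.clip(prop, -_LOG_SIG_BOUND, _LOG_SIG_BOUND)
            dll = self.lik * (
                -ctx.T_p[None] * (safe - self.log_sigma)
                - 0.5 * self.ssr * (np.exp(-2 * safe) - np.exp(-2 * self.log_sigma))
            ).sum(axis=1)
            dlp = np.where(
                np.abs(prop).max(axis=1) > _LOG_SIG_BOUND, -np.inf, dlp
            )
            acc = self._mh_accept(step_name, dll + dlp, (C,))
            self.log_sigma = np.where(acc[:, None], prop, self.log_sigma)
            self.mu_log_sigma = np.where(acc, mu_new, self.mu_log_sigma)
            if tau_new is not None:
                self.log_tau_log_sigma = np.where(acc, tau_new, self.log_tau_log_sigma)

    def _update_joint_level_move(self, scale_mult: float = 1.0):
        """Adaptive joint translation of the group-level block.

        The posterior carries a strong, dataset-specific ridge coupling the
        group probit mean of alpha, the group mean of log h, and the group
        rule-weight means (a higher rule share trades against the similarity
        gradient and rescaled weights); axis-aligned moves cross it
        extremely slowly.  This move proposes a correlated shift of
        v = (mu, mu_log_h, mu_beta) from a per-chain (K+2)-dimensional
        covariance estimated during burn-in (chain-pooled at freeze),
        applied as a pure translation: mu and every theta shift together,
        mu_log_h and every log h shift together, and mu_beta shifts
        directly (the individual rule weights are marginalized in the
        acceptance).  All hierarchy prior terms cancel and the Jacobian is
        one; only the marginal likelihood and the hyperpriors enter."""
        ctx, pr = self.ctx, self.ctx.priors
        C, K = self.C, self.K
        z = self.rng.standard_normal((C, K + 2))
        eps = (
            np.einsum("cij,cj->ci", self._joint_chol, z)
            * self.step["joint_level"][:, None]
            * scale_mult
        )
        theta_p = self.theta + eps[:, 0][:, None]
        a_p = ndtr(theta_p)
        logh_p = self.log_h + eps[:, 1][:, None]
        mu_b_p = self.mu_beta + eps[:, 2:]
        oob = np.abs(logh_p).max(axis=1) > _LOG_H_BOUND
        JE_prop = _je_kernel(
            np.exp(np.clip(logh_p, -_LOG_H_BOUND, _LOG_H_BOUND)), ctx.Dex, ctx.yex
        )
        JE_t_prop = np.ascontiguousarray(ctx.trial_gather(JE_prop))

        if self.lik:
            stats_prop = self._je_stats(JE_t_prop)
            dll = (
                self._marginal_rule_ll(a_p, stats_prop, mu_b_p)
                - self._marginal_rule_ll(self.alpha, self._stats)
            ).sum(axis=1)
        else:
            stats_prop = self._stats
            dll = np.zeros(C)
        dlp = (
            _norm_logpdf(self.mu + eps[:, 0], pr.mu_loc, pr.mu_scale)
            - _norm_logpdf(self.mu, pr.mu_loc, pr.mu_scale)
            + _norm_logpdf(self.mu_log_h + eps[:, 1], pr.mu_log_h_loc, pr.mu_log_h_scale)
            - _norm_logpdf(self.mu_log_h, pr.mu_log_h_loc, pr.mu_log_h_scale)
        )
        dlp += (
            _norm_logpdf(mu_b_p, pr.mu_beta_loc[None, :], pr.mu_beta_scale[None, :])
            - _norm_logpdf(
                self.mu_beta, pr.mu_beta_loc[None, :], pr.mu_beta_scale[None, :]
            )
        ).sum(axis=1)
        dlp = np.where(oob, -np.inf, dlp)
        acc = self._mh_accept("joint_level", dll + dlp, (C,))
        a2 = acc[:, None]
        self.theta = np.where(a2, theta_p, self.theta)
        self.alpha = np.where(a2, a_p, self.alpha)
        self.mu = np.where(acc, self.mu + eps[:, 0], self.mu)
        self.log_h = np.where(a2, logh_p, self.log_h)
        self.mu_log_h = np.where(acc, self.mu_log_h + eps[:, 1], self.mu_log_h)
        self.mu_beta = np.where(a2, mu_b_p, self.mu_beta)
        self.JE = np.where(acc[:, None, None], JE_prop, self.JE)
        self.JE_t = np.ascontiguousarray(np.where(a2, JE_t_prop, self.JE_t))
        if self.lik:
            self._stats = tuple(
                np.where(a2 if cur.ndim == 2 else acc[:, None, None], new, cur)
                for cur, new in zip(self._stats, stats_prop)
            )

    def _joint_state(self) -> np.ndarray:
        return np.concatenate(
            [self.mu[:, None], self.mu_log_h[:, None], self.mu_beta], axis=1
        )

    def _adapt_joint_cov(self):
        """Exponentially weighted per-chain covariance of the group-level
        block (mu, mu_log_h, mu_beta), updated during burn-in only."""
        x = self._joint_state()  # (C, K+2)
        lam = 0.995
        d = x - self._joint_mean
        self._joint_mean += (1 - lam) * d
        self._joint_cov = lam * self._joint_cov + (1 - lam) * np.einsum(
            "ci,cj->cij", d, d
        )
        dim = x.shape[1]
        cov = self._joint_cov + 1e-6 * np.eye(dim)[None]
        self._joint_chol = np.linalg.cholesky(cov)

    def _update_normal_hyper(self, x, mu, log_tau, mu0, s0, tau_scale, step_name):
        """Gibbs for the group mean, log random walk for the group scale.
        ``x`` is (C, P) or (C, P, K); mu/log_tau match its trailing shape."""
        P = x.shape[1]
        tau2 = np.exp(2 * log_tau)
        prec = 1.0 / s0**2 + P / tau2
        mean = (mu0 / s0**2 + x.sum(axis=1) / tau2) / prec
        mu_new = mean + self.rng.standard_normal(mu.shape) / np.sqrt(prec)

        prop = log_tau + self.step[step_name] * self.rng.standard_normal(log_tau.shape)

        def ll(lt):
            t2 = np.exp(2 * lt)
            sse = ((x - np.expand_dims(mu_new, 1)) ** 2).sum(axis=1)
            return (
                -P * lt
                - sse / (2 * t2)
                + _halfnorm_logpdf(np.exp(lt), tau_scale)
                + lt
            )

        acc = self._mh_accept(step_name, ll(prop) - ll(log_tau), log_tau.shape)
        return mu_new, np.where(acc, prop, log_tau)

    def _update_group_hypers(self):
        pr = self.ctx.priors
        if self.ctx.has_rule and pr.fix_tau_beta is not None:
            tau2 = np.exp(2 * self.log_tau_beta)
            prec = 1.0 / pr.mu_beta_scale[None, :] ** 2 + self.P / tau2
            mean = (
                pr.mu_beta_loc[None, :] / pr.mu_beta_scale[None, :] ** 2
                + self.beta.sum(axis=1) / tau2
            ) / prec
            self.mu_beta = mean + self.rng.standard_normal(mean.shape) / np.sqrt(prec)
        elif self.ctx.has_rule:
            self.mu_beta, self.log_tau_beta = self._update_normal_hyper(
                self.beta,
                self.mu_beta,
                self.log_tau_beta,
                pr.mu_beta_loc[None, :],
                pr.mu_beta_scale[None, :],
                pr.tau_beta_scale[None, :],
                "tau_beta",
            )
        if self.ctx.has_ex:
            self.mu_log_h, self.log_tau_log_h = self._update_normal_hyper(
                self.log_h,
                self.mu_log_h,
                self.log_tau_log_h,
                pr.mu_log_h_loc,
                pr.mu_log_h_scale,
                pr.tau_log_h_scale,
                "tau_log_h",
            )
        self.mu_log_sigma, self.log_tau_log_sigma = self._update_normal_hyper(
            self.log_sigma,
            self.mu_log_sigma,
            self.log_tau_log_sigma,
            pr.mu_log_sigma_loc,
            pr.mu_log_sigma_scale,
            pr.tau_log_sigma_scale,
            "tau_log_sigma",
        )

    def _iterate(self):
        # the theta and log_h blocks marginalize beta, so beta must be
        # redrawn from its full conditional before any block conditions on it
        ctx = self.ctx
        if ctx.has_alpha:
            for _ in range(2):  # cheap with the marginal kernel; theta is
                self._update_theta()  # a mixing bottleneck
        if ctx.has_ex:
            self._update_log_h()
        if ctx.has_alpha:
            self._update_theta_interweave()
        if ctx.has_ex:
            self._update_h_cluster()
        if ctx.has_alpha and ctx.has_ex:
            for _ in range(3):
                self._update_joint_level_move()
        if ctx.has_rule:
            self._update_beta()
        else:
            self._recompute_ssr()
        self._update_log_sigma()
        self._update_ls_cluster()
        self._update_ls_cluster()
        if ctx.has_alpha:
            self._update_theta_hypers()
        self._update_group_hypers()

    # -- main loop -----------------------------------------------------------

    def run(self) -> dict[str, np.ndarray]:
        """Burn in (with adaptation) and collect the configured draws."""
        ctx, st = self.ctx, self.st
        window = 50
        for it in range(1, st.burn_in + 1):
            self._iterate()
            if ctx.has_alpha and ctx.has_ex:
                self._adapt_joint_cov()
            if it % window == 0:
                self._adapt(window)
            if it == st.burn_in and ctx.has_alpha and ctx.has_ex:
                # freeze the joint proposal on the chain-pooled covariance:
                # every chain targets the same posterior, and pooling
                # protects a chain whose own adaptation lagged in burn-in
                dim = self._joint_cov.shape[-1]
                pooled = self._joint_cov.mean(axis=0) + 1e-6 * np.eye(dim)
                self._joint_chol = np.tile(
                    np.linalg.cholesky(pooled), (self.C, 1, 1)
                )
        return self.collect(st.n_kept, st.thin)

    def collect(self, n_kept: int, thin: int) -> dict[str, np.ndarray]:
        """Draw ``n_kept`` further samples (post burn-in; no adaptation).
        Callable repeatedly to extend the chains."""
        ctx = self.ctx
        C, P, K, S = self.C, self.P, self.K, n_kept
        keep: dict[str, np.ndarray] = {"log_sigma": np.empty((C, S, P))}
        if ctx.has_alpha:
            keep.update(
                theta=np.empty((C, S, P)),
                alpha=np.empty((C, S, P)),
                mu=np.empty((C, S)),
                sigma_theta=np.empty((C, S)),
                mu_alpha_1=np.empty((C, S)),
                phi_mu_alpha_1=np.empty((C, S)),
            )
            if ctx.n_cond == 2:
                keep.update(
                    delta=np.empty((C, S)),
                    mu_alpha_2=np.empty((C, S)),
                    phi_mu_alpha_2=np.empty((C, S)),
                )
        if ctx.has_rule:
            keep.update(beta=np.empty((C, S, P, K)), mu_beta=np.empty((C, S, K)),
                        tau_beta=np.empty((C, S, K)))
        if ctx.has_ex:
            keep.update(log_h=np.empty((C, S, P)), mu_log_h=np.empty((C, S)),
                        tau_log_h=np.empty((C, S)))
        keep.update(mu_log_sigma=np.empty((C, S)), tau_log_sigma=np.empty((C, S)))

        for i in range(S):
            for _ in range(thin):
                self._iterate()
            keep["log_sigma"][:, i] = self.log_sigma
            if ctx.has_alpha:
                stheta = np.exp(self.log_sigma_theta)
                delta = self.delta if ctx.n_cond == 2 else np.zeros(C)
                mcond = ctx.cond_means(self.mu, delta, stheta)
                keep["theta"][:, i] = self.theta
                keep["alpha"][:, i] = self.alpha
                keep["mu"][:, i] = self.mu
                keep["sigma_theta"][:, i] = stheta
                keep["mu_alpha_1"][:, i] = mcond[:, 0]
                keep["phi_mu_alpha_1"][:, i] = ndtr(mcond[:, 0])
                if ctx.n_cond == 2:
                    keep["delta"][:, i] = self.delta
                    keep["mu_alpha_2"][:, i] = mcond[:, 1]
                    keep["phi_mu_alpha_2"][:, i] = ndtr(mcond[:, 1])
            if ctx.has_rule:
                keep["beta"][:, i] = self.beta
                keep["mu_beta"][:, i] = self.mu_beta
                keep["tau_beta"][:, i] = np.exp(self.log_tau_beta)
            if ctx.has_ex:
                keep["log_h"][:, i] = self.log_h
                keep["mu_log_h"][:, i] = self.mu_log_h
                keep["tau_log_h"][:, i] = np.exp(self.log_tau_log_h)
            keep["mu_log_sigma"][:, i] = self.mu_log_sigma
            keep["tau_log_sigma"][:, i] = np.exp(self.log_tau_log_sigma)
        return keep


def sample_posterior(
    data: pd.DataFrame,
    cues: CueMatrix,
    ex: ExemplarSet,
    priors: Priors | None = None,
    settings: SamplerSettings | None = None,
    model: str = "rulexj",
    condition_order: tuple[str, str] | None = None,
    prior_only: bool = False,
    metric: str = "euclidean",
) -> RulExJPosterior:
    """Draw from the posterior of the hierarchical RulEx-J model (or of its
    pure-rule / pure-exemplar restriction).

    ``condition_order`` fixes which condition label is condition 1 (the one
    expected to carry the larger alpha); by default labels are taken in
    sorted order.  ``prior_only=True`` drops the likelihood so the sampler
    targets the prior (a prior-recovery diagnostic).

    Convergence is assessed with the split-chain R-hat on all group-level
    parameters and per-participant alphas; a posterior with any R-hat above
    1.01 is returned flagged (``converged=False``), never silently accepted.
    """
    settings = settings or SamplerSettings()
    ctx = _ModelContext(
        data, cues, ex, priors, model, condition_order, prior_only=prior_only,
        metric=metric,
    )
    sampler = _GibbsSampler(ctx, settings)
    chains = sampler.run()

    diags: dict[str, float] = {}
    for name, x in chains.items():
        if x.ndim == 2:
            diags[name] = rhat(x)
        elif name == "alpha":
            for p in range(x.shape[2]):
                diags[f"alpha[{p}]"] = rhat(x[:, :, p])
    converged = all(r <= 1.01 for r in diags.values())
    if not converged:
        worst = max(diags, key=diags.get)
        warnings.warn(
            f"MCMC may not have converged: max R-hat {diags[worst]:.3f} "
            f"({worst})",
            RuntimeWarning,
            stacklevel=2,
        )
    post = RulExJPosterior(
        chains=chains,
        rhat=diags,
        settings=settings,
        participant_ids=ctx.pids,
        conditions=ctx.conditions,
        model=model,
        converged=converged,
        delta_prior=ctx.priors.delta_prior(),
        _ctx=ctx,
        _sampler=sampler,
    )
    return post


def _rhat_diags(chains: dict[str, np.ndarray]) -> dict[str, float]:
    diags: dict[str, float] = {}
    for name, x in chains.items():
        if x.ndim == 2:
            diags[name] = rhat(x)
        elif name == "alpha":
            for p in range(x.shape[2]):
                diags[f"alpha[{p}]"] = rhat(x[:, :, p])
    return diags


def extend_posterior(post: RulExJPosterior, n_more: int) -> RulExJPosterior:
    """Continue sampling from where the chains stopped and append ``n_more``
    kept draws per chain (the standard remedy for chains that have not yet
    reached the convergence standard: run them longer, never re-seed)."""
    if post._sampler is None:
        raise ValueError("posterior does not carry a live sampler state")
    more = post._sampler.collect(n_more, post.settings.thin)
    chains = {
        k: np.concatenate([post.chains[k], more[k]], axis=1) for k in post.chains
    }
    diags = _rhat_diags(chains)
    converged = all(r <= 1.01 for r in diags.values())
    settings = SamplerSettings(
        n_chains=post.settings.n_chains,
        n_kept=post.settings.n_kept + n_more,
        burn_in=post.settings.burn_in,
        thin=post.settings.thin,
        seed=post.settings.seed,
    )
    return RulExJPosterior(
        chains=chains,
        rhat=diags,
        settings=settings,
        participant_ids=post.participant_ids,
        conditions=post.conditions,
        model=post.model,
        converged=converged,
        delta_prior=post.delta_prior,
        _ctx=post._ctx,
        _sampler=post._sampler,
    )


def posterior_draws_matrix(post: RulExJPosterior) -> np.ndarray:
    """Pooled draws arranged as rows in the sampler's unconstrained
    parameter layout (the input bridge sampling needs)."""
    ctx = post._ctx
    cols = []
    for name, off, size in ctx.layout:
        if name == "beta":
            cols.append(post.stacked("beta").reshape(-1, ctx.P * ctx.K))
        elif name == "log_sigma_theta":
            cols.append(np.log(post.stacked("sigma_theta"))[:, None])
        elif name == "log_tau_beta":
            cols.append(np.log(post.stacked("tau_beta")))
        elif name == "log_tau_log_h":
            cols.append(np.log(post.stacked("tau_log_h"))[:, None])
        elif name == "log_tau_log_sigma":
            cols.append(np.log(post.stacked("tau_log_sigma"))[:, None])
        else:
            x = post.stacked(name)
            cols.append(x[:, None] if x.ndim == 1 else x)
    return np.column_stack(cols)


def summarize_posterior(post: RulExJPosterior, prob: float = 0.95) -> pd.DataFrame:
    """Posterior mean, SD, HDI and R-hat for the group-level parameters."""
    rows = []
    for name, x in post.chains.items():
        if x.ndim != 2:
            continue
        flat = x.ravel()
        lo, hi = hdi(flat, prob)
        rows.append(
            {
                "parameter": name,
                "mean": flat.mean(),
                "sd": flat.std(ddof=1),
                f"hdi_{prob:g}_lower": lo,
                f"hdi_{prob:g}_upper": hi,
                "rhat": post.rhat.get(name, np.nan),
            }
        )
    return pd.DataFrame(rows)


def write_posterior(post: RulExJPosterior, out_dir: str) -> None:
    """Write group-level chains as columnar delimited text plus a JSON
    summary (means, SDs, HDIs, R-hat)."""
    os.makedirs(out_dir, exist_ok=True)
    scalar = {k: v for k, v in post.chains.items() if v.ndim == 2}
    C, S = next(iter(scalar.values())).shape
    df = pd.DataFrame(
        {"chain": np.repeat(np.arange(C), S), "draw": np.tile(np.arange(S), C)}
    )
    for k, v in scalar.items():
        df[k] = v.ravel()
    df.to_csv(os.path.join(out_dir, "chains.csv"), index=False)
    summ = summarize_posterior(post)
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(
            {
                "model": post.model,
                "conditions": post.conditions,
                "converged": post.converged,
                "settings": {
                    "n_chains": post.settings.n_chains,
                    "n_kept": post.settings.n_kept,
                    "burn_in": post.settings.burn_in,
                    "thin": post.settings.thin,
                    "seed": post.settings.seed,
                },
                "parameters": summ.to_dict(orient="records"),
                "max_rhat": max(post.rhat.values()),
            },
            fh,
            indent=2,
        )


def read_judgments(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in JUDGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"judgment table missing columns {missing}")
    return df


def write_judgments(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False)


def probit(p: float | np.ndarray) -> float | np.ndarray:
    return ndtri(p)
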