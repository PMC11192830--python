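"""Generators: latent spaces, block-design ratings, exemplar selection,
judgment simulation."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from scipy.special import ndtr, ndtri
from scipy.stats import spearmanr

from rulexj import model, synthetic


class TestLatentConfig:
    def test_coords_column_centered(self):
        cfg = synthetic.make_latent_config(32, 3, "linear", seed=0)
        assert cfg.coords.shape == (32, 3)
        assert np.all(np.abs(cfg.coords.mean(axis=0)) < 1e-12)

    def test_linear_criterion_is_exactly_linear_in_coords(self):
        cfg = synthetic.make_latent_config(20, 3, "linear", seed=1)
        X = np.column_stack([np.ones(20), cfg.coords])
        coef, *_ = np.linalg.lstsq(X, cfg.criterion, rcond=None)
        fitted = X @ coef
        assert np.corrcoef(fitted, cfg.criterion)[0, 1] > 1 - 1e-12

    def test_nonlinear_criterion_not_linearly_reconstructible(self):
        # adjusted R^2 of a linear additive fit stays below 1 in every run
        for seed in range(100):
            cfg = synthetic.make_latent_config(32, 3, "nonlinear", seed=seed)
            X = np.column_stack([np.ones(32), cfg.coords])
            coef, *_ = np.linalg.lstsq(X, cfg.criterion, rcond=None)
            resid = cfg.criterion - X @ coef
            ss_res = np.sum(resid**2)
            ss_tot = np.sum((cfg.criterion - cfg.criterion.mean()) ** 2)
            r2 = 1 - ss_res / ss_tot
            adj = 1 - (1 - r2) * (32 - 1) / (32 - 3 - 1)
            assert adj < 1 - 1e-6

    def test_criterion_range_respected(self):
        cfg = synthetic.make_latent_config(32, 3, "nonlinear", seed=5)
        assert cfg.criterion.min() == pytest.approx(24.0)
        assert cfg.criterion.max() == pytest.approx(125.0)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            synthetic.make_latent_config(2, 3, "linear", seed=0)
        with pytest.raises(ValueError):
            synthetic.make_latent_config(10, 0, "linear", seed=0)


class TestBlockDesign:
    def test_study_design_counts(self):
        # 32 stimuli: 496 unordered pairs; groups of 4 raters -> 124 each
        assignment = synthetic.assign_pairs_bibd(32, 4, 8, seed=0)
        for rater, pairs in assignment.items():
            assert len(pairs) == 124
            assert len(set(pairs)) == 124  # no duplicates within a rater
        union = set().union(*(assignment[r] for r in range(4)))
        assert len(union) == 496  # a complete group covers all pairs

    def test_every_complete_group_covers_all_pairs(self):
        n, gs = 10, 3
        K = n * (n - 1) // 2
        assignment = synthetic.assign_pairs_bibd(n, gs, 9, seed=3)
        for g in range(3):
            union = set().union(*(assignment[g * gs + i] for i in range(gs)))
            assert len(union) == K

    def test_group_size_one_is_complete_design(self):
        assignment = synthetic.assign_pairs_bibd(8, 1, 3, seed=1)
        for pairs in assignment.values():
            assert len(pairs) == 28

    def test_reproducible(self):
        a = synthetic.assign_pairs_bibd(12, 4, 8, seed=9)
        b = synthetic.assign_pairs_bibd(12, 4, 8, seed=9)
        assert a == b


class TestSimilarityRatings:
    def test_ratings_are_integers_in_scale(self, ratings32):
        r = ratings32["rating"]
        assert r.dtype.kind == "i"
        assert r.between(1, 7).all()

    def test_noiseless_endpoints(self):
        cfg = synthetic.make_latent_config(8, 2, "linear", seed=2)
        params = synthetic.SimRatingParams(
            n_raters=1, group_size=1, noise_sd=0.0, seed=0
        )
        df = synthetic.simulate_similarity_ratings(cfg, params)
        D = cdist(cfg.coords, cfg.coords)
        labels = np.array(cfg.labels)
        dist = np.array(
            [
                D[np.where(labels == a)[0][0], np.where(labels == b)[0][0]]
                for a, b in zip(df.stim_a, df.stim_b)
            ]
        )
        assert df.rating[np.argmax(dist)] == 1
        assert df.rating[np.argmin(dist)] == 7

    def test_noiseless_ratings_anticorrelate_with_distance(self):
        cfg = synthetic.make_latent_config(8, 2, "linear", seed=4)
        params = synthetic.SimRatingParams(
            n_raters=1, group_size=1, noise_sd=0.0, seed=0
        )
        df = synthetic.simulate_similarity_ratings(cfg, params)
        D = cdist(cfg.coords, cfg.coords)
        idx = {s: i for i, s in enumerate(cfg.labels)}
        dist = [D[idx[a], idx[b]] for a, b in zip(df.stim_a, df.stim_b)]
        rho = spearmanr(df.rating, dist)[0]
        # perfect reversal up to rounding ties
        assert rho < -0.97

    def test_duplicated_stimulus_rates_top_of_scale(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        cfg = synthetic.LatentConfig(
            coords=coords, criterion=np.arange(4.0), seed=0
        )
        params = synthetic.SimRatingParams(
            n_raters=1, group_size=1, noise_sd=0.0, seed=0
        )
        df = synthetic.simulate_similarity_ratings(cfg, params)
        pair = df[(df.stim_a == "s0") & (df.stim_b == "s1")]
        assert (pair.rating == 7).all()

    def test_degenerate_configuration_rejected(self):
        cfg = synthetic.LatentConfig(
            coords=np.zeros((4, 2)), criterion=np.arange(4.0), seed=0
        )
        with pytest.raises(ValueError, match="degenerate"):
            synthetic.simulate_similarity_ratings(
                cfg, synthetic.SimRatingParams(n_raters=1, seed=0)
            )

    def test_bit_reproducible(self, latent32):
        p = synthetic.SimRatingParams(n_raters=8, seed=123)
        a = synthetic.simulate_similarity_ratings(latent32, p)
        b = synthetic.simulate_similarity_ratings(latent32, p)
        pd.testing.assert_frame_equal(a, b)

    def test_exponential_link_is_monotone(self):
        cfg = synthetic.make_latent_config(8, 2, "linear", seed=4)
        params = synthetic.SimRatingParams(
            n_raters=1, group_size=1, noise_sd=0.0, seed=0, link="exponential"
        )
        df = synthetic.simulate_similarity_ratings(cfg, params)
        D = cdist(cfg.coords, cfg.coords)
        idx = {s: i for i, s in enumerate(cfg.labels)}
        dist = [D[idx[a], idx[b]] for a, b in zip(df.stim_a, df.stim_b)]
        assert spearmanr(df.rating, dist)[0] < -0.9


class TestTrainingPairs:
    def test_one_tied_pair_gives_65_trials(self):
        # 12 exemplars with exactly one criterion tie: C(12,2) - 1 = 65
        crit = np.array(
            [24.0, 30.0, 35.0, 43.0, 43.0, 50.0, 60.0, 70.0, 80.0, 95.0, 110.0, 125.0]
        )
        pairs = synthetic.training_pairs(crit)
        assert len(pairs) == 65

    def test_no_ties_gives_all_pairs(self):
        pairs = synthetic.training_pairs(np.arange(12.0))
        assert len(pairs) == 66

    def test_tie_detection_after_rounding(self):
        assert len(synthetic.training_pairs(np.array([1.01, 1.04, 2.0]))) == 2


class TestSelectExemplars:
    def test_exhaustive_matches_large_random_search(self):
        rng = np.random.default_rng(0)
        cues = rng.standard_normal((10, 2))
        crit = 10 * cues[:, 0] + 5 * cues[:, 1] ** 2 + 50
        kw = dict(m=4, min_validity=0.5, min_range_frac=0.5)
        full = synthetic.select_exemplars(cues, crit, exhaustive=True, **kw)
        rand = synthetic.select_exemplars(
            cues, crit, n_candidate_sets=2000, seed=1, **kw
        )
        assert np.array_equal(full.indices, rand.indices)

    def test_linear_noiseless_rule_model_is_exact(self):
        rng = np.random.default_rng(3)
        cues = rng.standard_normal((16, 3))
        crit = 4.0 + cues @ np.array([2.0, -1.0, 0.5])
        sel = synthetic.select_exemplars(
            cues, crit, m=6, n_candidate_sets=50, seed=0,
            min_validity=0.0, min_range_frac=0.0,
        )
        # rule-only model reproduces a linear criterion exactly
        assert sel.rule_validity > 1 - 1e-10

    def test_no_admissible_set_raises(self):
        rng = np.random.default_rng(4)
        cues = rng.standard_normal((10, 2))
        crit = rng.standard_normal(10)  # criterion unrelated to cues
        with pytest.raises(ValueError, match="no admissible"):
            synthetic.select_exemplars(
                cues, crit, m=4, n_candidate_sets=20, seed=0, min_validity=0.999
            )


class TestSimulateJudgments:
    @pytest.fixture(scope="class")
    def setup(self, latent32):
        cfg = latent32
        cues = model.CueMatrix(labels=cfg.labels, values=cfg.coords)
        ex = model.ExemplarSet(
            labels=cfg.labels[:12],
            cue_vectors=cfg.coords[:12],
            criterion=cfg.criterion[:12],
        )
        return cues, ex

    def test_alpha_one_limit_reproduces_rule(self, setup):
        cues, ex = setup
        params = synthetic.JudgeSimParams(
            mu_alpha=(10.0, 10.0), sigma_theta=1e-6, sigma_resp=1e-12,
            beta0=50.0, beta=np.array([5.0, -3.0, 2.0]), seed=0,
            n_per_condition=2,
        )
        df = synthetic.simulate_judgments(cues, ex, params)
        jr = model.rule_prediction(cues.values, 50.0, np.array([5.0, -3.0, 2.0]))
        idx = {s: i for i, s in enumerate(cues.labels)}
        expected = np.array([jr[idx[s]] for s in df.stim_id])
        np.testing.assert_allclose(df.response, expected, atol=1e-6)

    def test_alpha_zero_limit_reproduces_exemplar(self, setup):
        cues, ex = setup
        params = synthetic.JudgeSimParams(
            mu_alpha=(-10.0, -10.0), sigma_theta=1e-6, sigma_resp=1e-12,
            h=2.0, seed=0, n_per_condition=2,
        )
        df = synthetic.simulate_judgments(cues, ex, params)
        je = np.asarray(model.exemplar_prediction(cues.values, ex, 2.0))
        idx = {s: i for i, s in enumerate(cues.labels)}
        expected = np.array([je[idx[s]] for s in df.stim_id])
        np.testing.assert_allclose(df.response, expected, atol=1e-6)

    def test_alpha_draws_match_probit_normal_mean(self, setup):
        # E[Phi(theta)] = Phi(mu / sqrt(1 + sigma_theta^2)) for theta ~ N(mu, s^2)
        cues, ex = setup
        params = synthetic.JudgeSimParams(seed=0, n_per_condition=39)
        alphas = {0: [], 1: []}
        for rep in range(50):
            df = synthetic.simulate_judgments(
                cues, ex, synthetic.JudgeSimParams(seed=rep, n_per_condition=39)
            )
            per = df.drop_duplicates("participant_id")
            for j, cond in enumerate(["comparison", "direct"]):
                alphas[j].extend(per.loc[per.condition == cond, "alpha_true"])
        for j, mu in enumerate(params.mu_alpha):
            target = ndtr(mu / np.sqrt(1 + params.sigma_theta**2))
            x = np.array(alphas[j])
            se = x.std(ddof=1) / np.sqrt(len(x))
            assert abs(x.mean() - target) < 3 * se + 1e-4

    def test_old_new_flags_match_exemplars(self, setup, latent32):
        cues, ex = setup
        df = synthetic.simulate_judgments(
            cues, ex, synthetic.JudgeSimParams(seed=1, n_per_condition=1)
        )
        assert set(df.loc[df.is_old, "stim_id"]) == set(ex.labels)
        assert len(df.loc[~df.is_old, "stim_id"].unique()) == 20
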