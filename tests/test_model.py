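"""Elastic Net fitting, shrinkage selection, thresholding and nested CV."""

import numpy as np
import pandas as pd
import pytest

from crsrad.model import (
    CVConfig,
    ElasticNetConfig,
    fit_elastic_net,
    lambda_grid,
    nested_cv_run,
    optimize_threshold,
    repeat_nested_cv,
    select_lambda,
)
from crsrad.synthetic import CohortSpec, generate_feature_cohort
from crsrad.tables import FeatureTable

from oracles import brute_threshold


def _standardized_toy(n=300, seed=0, effects=(1.5, -1.0)):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, len(effects)))
    logits = X @ np.array(effects)
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-logits))).astype(int)
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    return X, y


class TestElasticNetFit:
    def test_heavy_shrinkage_zeroes_coefficients(self):
        X, y = _standardized_toy()
        beta, b0 = fit_elastic_net(X, y, lam=100.0, alpha=0.5, tol=1e-8)
        assert np.all(beta == 0.0)
        prev = y.mean()
        assert 1 / (1 + np.exp(-b0)) == pytest.approx(prev, abs=1e-3)

    def test_near_unpenalized_matches_irls_oracle(self):
        """lambda -> 0 at alpha = 0 recovers the maximum-likelihood fit.

        Oracle: iteratively reweighted least squares run from scratch.
        """
        X, y = _standardized_toy(n=400, seed=1)
        beta, b0 = fit_elastic_net(X, y, lam=1e-8, alpha=0.0, tol=1e-10)

        w = np.zeros(X.shape[1] + 1)
        Xd = np.hstack([np.ones((len(y), 1)), X])
        for _ in range(60):
            p = 1 / (1 + np.exp(-(Xd @ w)))
            W = p * (1 - p)
            grad = Xd.T @ (y - p)
            H = (Xd * W[:, None]).T @ Xd
            step = np.linalg.solve(H, grad)
            w = w + step
            if np.max(np.abs(step)) < 1e-12:
                break
        assert b0 == pytest.approx(w[0], abs=1e-4)
        np.testing.assert_allclose(beta, w[1:], atol=1e-4)

    def test_ridge_symmetry_on_duplicated_column(self):
        X, y = _standardized_toy(n=300, seed=2, effects=(1.0,))
        Xdup = np.hstack([X, X])
        beta, _ = fit_elastic_net(Xdup, y, lam=0.05, alpha=0.0, tol=1e-8)
        assert beta[0] == pytest.approx(beta[1], abs=1e-4)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 2))
        with pytest.raises(ValueError):
            fit_elastic_net(X, np.ones(10, dtype=int), lam=0.1)


class TestLambdaPath:
    def test_grid_is_descending_and_positive(self):
        X, y = _standardized_toy()
        grid = lambda_grid(X, y, ElasticNetConfig())
        assert len(grid) == 50
        assert np.all(np.diff(grid) < 0)
        assert grid[-1] > 0

    def test_top_of_grid_gives_null_model(self):
        X, y = _standardized_toy()
        grid = lambda_grid(X, y, ElasticNetConfig())
        beta, _ = fit_elastic_net(X, y, grid[0], alpha=0.5)
        assert np.all(beta == 0.0)

    def test_monotone_shrinkage_along_grid(self):
        """Non-zero coefficient count is non-increasing in lambda (alpha > 0)."""
        X, y = _standardized_toy(n=200, seed=3, effects=(2.0, -1.5, 1.0, 0.0, 0.0))
        grid = lambda_grid(X, y, ElasticNetConfig())
        nnz = []
        for lam in grid[::5]:
            beta, _ = fit_elastic_net(X, y, lam, alpha=0.5, tol=1e-7)
            nnz.append(int((np.abs(beta) > 1e-8).sum()))
        # grid descends, so counts may only grow as lambda shrinks
        assert all(a <= b for a, b in zip(nnz, nnz[1:]))


class TestSelectLambda:
    def test_pure_noise_selects_strong_shrinkage(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(
            rng.standard_normal((80, 10)), columns=[f"n{i}" for i in range(10)]
        )
        y = rng.integers(0, 2, 80)
        while len(np.unique(y)) < 2:
            y = rng.integers(0, 2, 80)
        lam = select_lambda(X, y, seed=1)
        grid_top = lambda_grid(
            ((X - X.mean()) / X.std(ddof=1)).to_numpy(), y, ElasticNetConfig()
        )[0]
        assert lam > 0.1 * grid_top  # null model region of the path

    def test_strong_predictor_beats_null_deviance(self):
        rng = np.random.default_rng(5)
        n = 300
        x = rng.standard_normal(n)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-2.5 * x))).astype(int)
        X = pd.DataFrame({"x": x, "junk": rng.standard_normal(n)})
        lam = select_lambda(X, y, seed=2)
        Z = ((X - X.mean()) / X.std(ddof=1)).to_numpy()
        grid = lambda_grid(Z, y, ElasticNetConfig())
        assert lam < grid[5]  # well below the null-model end of the path
        # and the selected fit strictly beats the null deviance
        beta, b0 = fit_elastic_net(Z, y, lam)
        p = 1 / (1 + np.exp(-(Z @ beta + b0)))
        dev = -2 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        p0 = y.mean()
        null_dev = -2 * np.mean(y * np.log(p0) + (1 - y) * np.log(1 - p0))
        assert dev < null_dev

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.standard_normal((60, 4)), columns=list("abcd"))
        y = np.array([0, 1] * 30)
        assert select_lambda(X, y, seed=3) == select_lambda(X, y, seed=3)


class TestThreshold:
    def test_perfect_separation_gmean_one(self):
        scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        labels = np.array([0, 0, 0, 1, 1, 1])
        tau = optimize_threshold(scores, labels)
        oracle_tau, oracle_g = brute_threshold(scores, labels)
        assert oracle_g == 1.0
        assert tau == oracle_tau == 0.5

    def test_degenerate_identical_scores(self):
        tau = optimize_threshold(np.full(8, 0.4), np.array([0, 1] * 4))
        assert tau == 0.5

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.uniform(size=8), 2)
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        rng.shuffle(labels)
        if len(np.unique(scores)) < 2:
            pytest.skip("degenerate draw")
        tau = optimize_threshold(scores, labels)
        oracle_tau, _ = brute_threshold(scores, labels)
        assert tau == pytest.approx(oracle_tau)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            optimize_threshold(np.array([0.1, 0.9]), np.array([1, 1]))


class TestNestedCV:
    def test_fold_bookkeeping_is_leakage_free(self, discovery_table):
        run = nested_cv_run(discovery_table, permutation_seed=11)
        n = discovery_table.n_patients
        all_test = np.concatenate(run.fold_test_rows)
        assert sorted(all_test) == list(range(n))  # each row tested exactly once
        for tr, te in zip(run.fold_train_rows, run.fold_test_rows):
            assert set(tr).isdisjoint(te)
            assert len(set(tr) | set(te)) == n

    def test_outer_test_rows_do_not_shape_models(self, discovery_table):
        """Corrupting outer-test features changes predictions, not parameters."""
        run = nested_cv_run(discovery_table, permutation_seed=13)
        corrupted_X = discovery_table.features.copy()
        te0 = run.fold_test_rows[0]
        rng = np.random.default_rng(0)
        corrupted_X.iloc[te0] = rng.standard_normal(corrupted_X.iloc[te0].shape)
        corrupted = FeatureTable(corrupted_X, discovery_table.labels)
        run2 = nested_cv_run(corrupted, permutation_seed=13)
        m1, m2 = run.models[0], run2.models[0]
        assert m1.feature_names == m2.feature_names
        np.testing.assert_allclose(m1.beta, m2.beta)
        assert m1.lam == m2.lam and m1.tau == m2.tau
        assert not np.allclose(
            run.outer_scores[te0], run2.outer_scores[te0]
        )

    def test_repetition_and_instance_counts(self, discovery_table):
        res = repeat_nested_cv(discovery_table, CVConfig(n_repetitions=2, base_seed=9))
        assert res.n_instances == 10  # 2 repetitions x 5 outer folds
        assert len(res.metrics) == 2

    def test_identical_base_seed_reproduces_metrics(self, discovery_table):
        cfg = CVConfig(n_repetitions=2, base_seed=21)
        a = repeat_nested_cv(discovery_table, cfg)
        b = repeat_nested_cv(discovery_table, cfg)
        pd.testing.assert_frame_equal(a.metrics, b.metrics)
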