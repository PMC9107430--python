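"""Penalised logistic path solver, CV penalty choice and the stability loop."""

import shutil
import subprocess
import textwrap

import numpy as np
import pytest
import statsmodels.api as sm

from fcreact.selection import (SelectionConfig, choose_lambda_cv, lambda_max,
                               make_lambda_grid, penalized_logistic_path,
                               select_from_matrix, stratified_subsample)


def _logistic_data(n=40, p=3, seed=3, beta=None):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    if beta is None:
        beta = np.zeros(p)
        beta[: min(2, p)] = [1.0, -0.5][: min(2, p)]
    prob = 1.0 / (1.0 + np.exp(-(X @ beta)))
    y = (rng.random(n) < prob).astype(float)
    return X, y


class TestPenalizedPath:
    def test_all_slopes_exactly_zero_at_and_above_lambda_max(self):
        X, y = _logistic_data()
        lmax = lambda_max(X, y)
        path = penalized_logistic_path(X, y, np.array([10 * lmax, lmax]),
                                       standardize=False)
        assert np.all(path.coefs == 0.0)

    def test_tiny_penalty_matches_unpenalized_mle(self):
        X, y = _logistic_data(n=40, p=3)
        lmax = lambda_max(X, y)
        path = penalized_logistic_path(X, y, np.array([lmax, 1e-8 * lmax]),
                                       standardize=False, tol=1e-12)
        mle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        fitted = np.r_[path.intercepts[-1], path.coefs[-1]]
        assert np.max(np.abs(fitted - mle.params)) < 1e-4

    def test_duplicated_feature_shares_weight(self):
        X, y = _logistic_data(n=60, p=4, seed=9)
        lmax = lambda_max((X - X.mean(0)) / X.std(0), y)
        grid = np.array([0.3 * lmax])
        single = penalized_logistic_path(X, y, grid, tol=1e-11)
        Xdup = np.column_stack([X, X[:, 0]])
        dup = penalized_logistic_path(Xdup, y, grid, tol=1e-11)
        shared = abs(dup.coefs[0, 0]) + abs(dup.coefs[0, 4])
        assert shared == pytest.approx(abs(single.coefs[0, 0]), rel=0.05, abs=1e-4)

    def test_single_class_rejected(self):
        X, _ = _logistic_data()
        with pytest.raises(ValueError, match="two classes"):
            penalized_logistic_path(X, np.ones(len(X)))

    def test_constant_feature_dropped_with_warning(self):
        X, y = _logistic_data(n=50, p=3)
        X[:, 1] = 2.5
        with pytest.warns(UserWarning, match="constant"):
            path = penalized_logistic_path(X, y)
        assert np.all(path.coefs[:, 1] == 0.0)

    def test_matches_r_glmnet_reference(self):
        """Independent oracle: glmnet on the identical penalty grid."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the glmnet cross-check")
        X, y = _logistic_data(n=52, p=12, seed=21)
        lmax = lambda_max(X, y)
        grid = lmax * np.array([1.0, 0.5, 0.2, 0.08, 0.03])
        path = penalized_logistic_path(X, y, grid, standardize=False, tol=1e-13)
        import tempfile, pathlib
        with tempfile.TemporaryDirectory() as td:
            td = pathlib.Path(td)
            np.savetxt(td / "X.tsv", X, delimiter="\t")
            np.savetxt(td / "y.tsv", y, fmt="%d")
            np.savetxt(td / "lam.tsv", grid)
            script = textwrap.dedent("""
                suppressMessages(library(glmnet))
                X <- as.matrix(read.table("X.tsv"))
                y <- scan("y.tsv", quiet=TRUE)
                lam <- scan("lam.tsv", quiet=TRUE)
                fit <- glmnet(X, y, family="binomial", alpha=1, lambda=lam,
                              standardize=FALSE, thresh=1e-14)
                out <- rbind(fit$a0, as.matrix(fit$beta))
                write.table(out, "coefs.tsv", row.names=FALSE, col.names=FALSE)
            """)
            (td / "run.R").write_text(script)
            subprocess.run(["Rscript", "run.R"], cwd=td, check=True,
                           capture_output=True)
            ref = np.loadtxt(td / "coefs.tsv")   # (p+1) x n_lambda
        ours = np.vstack([path.intercepts, path.coefs.T])
        assert np.max(np.abs(ours - ref)) < 5e-4


class TestChooseLambdaCv:
    def test_pure_noise_prefers_upper_half_of_grid(self):
        hits = 0
        for s in range(50):
            rng = np.random.default_rng(s)
            X = rng.standard_normal((52, 20))
            y = np.r_[np.zeros(24), np.ones(28)]
            rng.shuffle(y)
            grid = make_lambda_grid(lambda_max((X - X.mean(0)) / X.std(0), y))
            _, idx = choose_lambda_cv(X, y, 10, grid, seed=s)
            hits += idx < 50
        assert hits >= 40  # >= 80% of repeats

    def test_separating_feature_is_admitted(self):
        admitted = 0
        for s in range(40):
            rng = np.random.default_rng(100 + s)
            X = rng.standard_normal((52, 10))
            y = np.r_[np.zeros(24), np.ones(28)]
            X[y == 1, 0] += 4.0   # margin far beyond the noise
            grid = make_lambda_grid(lambda_max((X - X.mean(0)) / X.std(0), y))
            lam, idx = choose_lambda_cv(X, y, 10, grid, seed=s)
            path = penalized_logistic_path(X, y, grid)
            admitted += path.coefs[idx, 0] != 0.0
        assert admitted >= 38  # >= 95% of repeats

    def test_deterministic_given_seed(self):
        X, y = _logistic_data(n=52, p=8, seed=5)
        grid = make_lambda_grid(lambda_max(X, y))
        a = choose_lambda_cv(X, y, 10, grid, seed=11)
        b = choose_lambda_cv(X, y, 10, grid, seed=11)
        assert a == b


class TestStratifiedSubsample:
    def test_floor_rule_on_24_28_at_80_percent(self):
        labels = np.r_[np.zeros(24), np.ones(28)]
        idx = stratified_subsample(labels, 0.8, seed=0)
        assert len(idx) == 41
        assert (labels[idx] == 0).sum() == 19
        assert (labels[idx] == 1).sum() == 22
        assert len(set(idx.tolist())) == 41

    def test_different_seeds_same_counts_different_members(self):
        labels = np.r_[np.zeros(24), np.ones(28)]
        a = stratified_subsample(labels, 0.8, seed=1)
        b = stratified_subsample(labels, 0.8, seed=2)
        assert len(a) == len(b) == 41
        assert not np.array_equal(a, b)

    def test_degenerate_class_rejected(self):
        labels = np.r_[np.zeros(2), np.ones(30)]
        with pytest.raises(ValueError):
            stratified_subsample(labels, 0.8, seed=0)


class TestStabilitySelect:
    def test_single_iteration_gives_binary_frequencies(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 10))
        y = np.r_[np.zeros(14), np.ones(16)]
        res = select_from_matrix(X, y, SelectionConfig(n_iter=1, cv_folds=5,
                                                       seed=0))
        assert set(np.unique(res.frequencies)).issubset({0.0, 1.0})

    def test_single_strong_feature_reaches_frequency_one(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 1))
        y = np.r_[np.zeros(20), np.ones(20)]
        X[y == 1, 0] += 3.0
        res = select_from_matrix(X, y, SelectionConfig(n_iter=20, cv_folds=5,
                                                       seed=1))
        assert res.frequencies[0] == 1.0

    def test_bitwise_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 25))
        y = np.r_[np.zeros(18), np.ones(22)]
        cfg = SelectionConfig(n_iter=10, cv_folds=5, seed=42)
        a = select_from_matrix(X, y, cfg)
        b = select_from_matrix(X, y, cfg)
        assert np.array_equal(a.frequencies, b.frequencies)
        assert a.iterations[3]["subsample"] == b.iterations[3]["subsample"]
        assert a.iterations[3]["lambda"] == b.iterations[3]["lambda"]

    def test_frequencies_follow_edge_reordering(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 15))
        y = np.r_[np.zeros(18), np.ones(22)]
        X[y == 1, 4] += 2.0
        cfg = SelectionConfig(n_iter=15, cv_folds=5, seed=7)
        a = select_from_matrix(X, y, cfg)
        perm = rng.permutation(15)
        b = select_from_matrix(X[:, perm], y, cfg)
        assert np.array_equal(a.frequencies[perm], b.frequencies)

    def test_planted_standardized_effect_recovered(self):
        """A d = 1.5 feature among 383 noise features is found and ranks first."""
        rng = np.random.default_rng(0)
        X = rng.standard_normal((52, 384))
        y = np.r_[np.zeros(24), np.ones(28)]
        X[y == 1, 0] += 1.5
        res = select_from_matrix(X, y, SelectionConfig(n_iter=100, seed=0))
        assert res.frequencies[0] >= 0.6
        assert res.ranking()[0] == 0

    def test_selected_flag_matches_threshold(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 8))
        y = np.r_[np.zeros(18), np.ones(22)]
        res = select_from_matrix(X, y, SelectionConfig(n_iter=10, cv_folds=5,
                                                       seed=3))
        assert np.array_equal(res.selected, res.frequencies >= 0.6)
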