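"""Tests for the CART-style regression tree and confirmatory OLS."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rhythmcomp import models as mdl


def brute_force_split(X, y, minbucket):
    """Independent oracle: plain double loop over predictors and thresholds."""
    n = len(y)
    best = None
    for j in range(X.shape[1]):
        uniq = np.unique(X[:, j])
        for a, b in zip(uniq[:-1], uniq[1:]):
            thr = (a + b) / 2
            left = X[:, j] < thr
            nl = left.sum()
            if nl < minbucket or n - nl < minbucket:
                continue
            yl, yr = y[left], y[~left]
            sse = np.sum((yl - yl.mean()) ** 2) + np.sum((yr - yr.mean()) ** 2)
            red = np.sum((y - y.mean()) ** 2) - sse
            if red <= 0:
                continue
            if best is None or red > best[2] + 1e-12:
                best = (j, thr, red)
    return best


class TestBestSplit:
    def test_separable_step_function(self):
        X = np.arange(1, 9, dtype=float).reshape(-1, 1)
        y = np.array([0, 0, 0, 0, 10, 10, 10, 10], dtype=float)
        j, thr, red = mdl.best_split(X, y, minbucket=4)
        assert (j, thr) == (0, 4.5)
        assert red == pytest.approx(np.sum((y - y.mean()) ** 2))

    def test_constant_response_has_no_split(self):
        X = np.arange(8, dtype=float).reshape(-1, 1)
        assert mdl.best_split(X, np.full(8, 3.0), minbucket=2) is None

    def test_minbucket_excludes_boundary_splits(self):
        X = np.arange(6, dtype=float).reshape(-1, 1)
        y = np.array([0, 0, 0, 0, 0, 10.0])
        assert mdl.best_split(X, y, minbucket=2) is not None
        found = mdl.best_split(X, y, minbucket=2)
        assert found[1] == 3.5  # isolated extreme cannot be cut off alone

    def test_matches_exhaustive_oracle_on_random_data(self, rng):
        for _ in range(50):
            n = rng.integers(8, 13)
            X = rng.standard_normal((n, 4))
            y = rng.standard_normal(n)
            ours = mdl.best_split(X, y, minbucket=4)
            oracle = brute_force_split(X, y, minbucket=4)
            if oracle is None:
                assert ours is None
            else:
                assert ours[0] == oracle[0]
                assert ours[1] == pytest.approx(oracle[1])
                assert ours[2] == pytest.approx(oracle[2])


def step_frame(n=20):
    X = pd.DataFrame({"a": np.arange(n, dtype=float), "b": np.zeros(n)})
    y = np.where(X["a"] < n / 2, 0.0, 10.0)
    return X, y


class TestGrowTree:
    def test_cp_one_always_root_only(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 3)), columns=list("abc"))
        y = X["a"] * 3 + rng.standard_normal(30)
        tree = mdl.grow_tree(X, y, mdl.TreeParams(cp=1.0))
        assert tree.n_splits == 0

    def test_step_data_yields_single_split(self):
        X, y = step_frame()
        tree = mdl.grow_tree(X, y, mdl.TreeParams(cp=0.1))
        assert tree.n_splits == 1
        assert tree.first_split_variable == "a"
        assert tree.root.left.mean_response == 0.0
        assert tree.root.right.mean_response == 10.0

    def test_node_below_two_minbuckets_stays_leaf(self, rng):
        X = pd.DataFrame({"a": np.arange(7, dtype=float)})
        y = np.where(X["a"] < 3, 0.0, 10.0)
        tree = mdl.grow_tree(X, y, mdl.TreeParams(cp=0.0))
        assert tree.n_splits == 0

    def test_child_sse_never_exceeds_parent(self, rng):
        X = pd.DataFrame(rng.standard_normal((40, 4)))
        y = rng.standard_normal(40) + 2 * X[0]

        tree = mdl.grow_tree(X, y, mdl.TreeParams(cp=0.05))

        def check(node):
            if node.is_leaf:
                return
            assert node.left.sse + node.right.sse <= node.sse + 1e-9
            check(node.left)
            check(node.right)

        check(tree.root)

    def test_cp_monotonicity_in_split_count(self, rng):
        X = pd.DataFrame(rng.standard_normal((40, 4)))
        y = 2 * X[0] - X[1] + 0.5 * rng.standard_normal(40)
        counts = [
            mdl.grow_tree(X, y, mdl.TreeParams(cp=cp)).n_splits
            for cp in (0.0, 0.02, 0.05, 0.1, 0.3, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_suppressing_repeated_predictors(self, rng):
        X = pd.DataFrame({"a": np.linspace(0, 1, 24)})
        y = np.select([X["a"] < 0.33, X["a"] < 0.66], [0.0, 10.0], 20.0)
        free = mdl.grow_tree(X, y, mdl.TreeParams(cp=0.01))
        capped = mdl.grow_tree(
            X, y, mdl.TreeParams(cp=0.01, allow_repeated_predictors=False)
        )
        assert free.n_splits >= 2
        assert capped.n_splits == 1

    def test_training_predictions_reduce_sse(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 4)))
        y = X[2] * 2 + rng.standard_normal(30)
        tree = mdl.grow_tree(X, y, mdl.TreeParams(cp=0.05))
        pred = mdl.predict_tree(tree, X)
        assert np.sum((y - pred) ** 2) <= np.sum((y - y.mean()) ** 2) + 1e-9

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            mdl.grow_tree(pd.DataFrame({"a": []}), [])


class TestPredictTree:
    def test_root_only_returns_grand_mean(self, rng):
        X = pd.DataFrame(rng.standard_normal((10, 2)), columns=["a", "b"])
        y = rng.standard_normal(10)
        tree = mdl.grow_tree(X, y, mdl.TreeParams(cp=1.0))
        assert mdl.predict_tree(tree, np.array([99.0, -99.0])) == pytest.approx(y.mean())

    def test_step_routing(self):
        X, y = step_frame()
        tree = mdl.grow_tree(X, y, mdl.TreeParams(cp=0.1))
        assert mdl.predict_tree(tree, np.array([2.0, 0.0])) == 0.0
        assert mdl.predict_tree(tree, np.array([16.0, 0.0])) == 10.0

    def test_leaf_identity_on_training_rows(self, rng):
        X = pd.DataFrame(rng.standard_normal((24, 3)), columns=list("abc"))
        y = 3 * X["a"] + rng.standard_normal(24)
        tree = mdl.grow_tree(X, y, mdl.TreeParams(cp=0.05))
        pred = mdl.predict_tree(tree, X)
        for leaf_mean in np.unique(pred):
            assert y[pred == leaf_mean].mean() == pytest.approx(leaf_mean)

    def test_missing_split_variable_rejected(self):
        X, y = step_frame()
        tree = mdl.grow_tree(X, y, mdl.TreeParams(cp=0.1))
        with pytest.raises(ValueError, match="a"):
            mdl.predict_tree(tree, pd.DataFrame({"b": [1.0]}))


class TestCvError:
    def test_separable_data_has_near_zero_cv_error(self):
        X, y = step_frame(40)
        err = mdl.cv_error(X, y, mdl.TreeParams(cp=0.1, seed=0))
        # at most the boundary observation per fold can be misrouted
        assert err < 0.2

    def test_pure_noise_cv_error_at_least_one_typically(self, rng):
        above = 0
        for i in range(30):
            X = pd.DataFrame(rng.standard_normal((30, 4)))
            y = rng.standard_normal(30)
            if mdl.cv_error(X, y, mdl.TreeParams(cp=0.1, seed=i)) >= 1.0:
                above += 1
        assert above >= 20

    def test_seeded_determinism(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 4)))
        y = rng.standard_normal(30)
        e1 = mdl.cv_error(X, y, mdl.TreeParams(cp=0.1), seed=42)
        e2 = mdl.cv_error(X, y, mdl.TreeParams(cp=0.1), seed=42)
        assert e1 == e2

    def test_too_few_rows_for_folds_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((5, 2)))
        with pytest.raises(ValueError, match="folds"):
            mdl.cv_error(X, rng.standard_normal(5), mdl.TreeParams(cv_folds=10))

    def test_cv_pruning_drops_weak_trees(self, rng):
        kept = 0
        for i in range(20):
            X = pd.DataFrame(rng.standard_normal((30, 4)))
            y = rng.standard_normal(30)
            tree = mdl.grow_tree(X, y, mdl.TreeParams(cp=0.1, prune="cv", seed=i))
            kept += tree.n_splits > 0
        assert kept <= 5  # null data: CV pruning removes most spurious splits


def ols_oracle(X, y):
    """Normal equations with scipy t/F distributions."""
    Xd = np.column_stack([np.ones(len(y)), X])
    XtX_inv = np.linalg.inv(Xd.T @ Xd)
    beta = XtX_inv @ Xd.T @ y
    resid = y - Xd @ beta
    n, p = len(y), Xd.shape[1] - 1
    dof = n - p - 1
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t), dof)
    sst = np.sum((y - y.mean()) ** 2)
    sse = resid @ resid
    r2 = 1 - sse / sst
    adj = 1 - (1 - r2) * (n - 1) / dof
    f = ((sst - sse) / p) / (sse / dof)
    fp = stats.f.sf(f, p, dof)
    return beta, se, t, pvals, f, fp, r2, adj


class TestFitOls:
    def test_perfect_fit(self):
        x = np.arange(5, dtype=float)
        fit = mdl.fit_ols(pd.DataFrame({"x": x}), 2 * x, include_interactions=False)
        assert fit.coefficients["x"] == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0) and fit.adj_r2 == pytest.approx(1.0)

    def test_fixture_matches_normal_equations_oracle(self, rng):
        X = pd.DataFrame(rng.standard_normal((10, 2)), columns=["u", "v"])
        y = 1.0 + 0.8 * X["u"] - 0.5 * X["v"] + 0.3 * X["u"] * X["v"]
        y = y + rng.standard_normal(10)
        fit = mdl.fit_ols(X, y, include_interactions=True)
        Xo = np.column_stack([X["u"], X["v"], X["u"] * X["v"]])
        beta, se, t, pv, f, fp, r2, adj = ols_oracle(Xo, y.to_numpy())
        got = [fit.coefficients[k] for k in fit.terms]
        assert np.allclose(got, beta, atol=1e-8)
        assert np.allclose([fit.std_errors[k] for k in fit.terms], se, atol=1e-8)
        assert np.allclose([fit.t_values[k] for k in fit.terms], t, atol=1e-8)
        assert np.allclose([fit.p_values[k] for k in fit.terms], pv, atol=1e-8)
        assert fit.f_statistic == pytest.approx(f, abs=1e-8)
        assert fit.f_pvalue == pytest.approx(fp, abs=1e-8)
        assert fit.r2 == pytest.approx(r2, abs=1e-10)
        assert fit.adj_r2 == pytest.approx(adj, abs=1e-10)
        assert fit.f_df == (3, 6)

    def test_adjusted_r2_identity(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 2)))
        y = rng.standard_normal(20)
        fit = mdl.fit_ols(X, y, include_interactions=True)
        p = len(fit.terms) - 1
        expect = 1 - (1 - fit.r2) * (fit.n - 1) / (fit.n - p - 1)
        assert fit.adj_r2 == pytest.approx(expect)

    def test_null_slopes_near_zero_at_large_n(self, rng):
        X = pd.DataFrame(rng.standard_normal((10_000, 2)), columns=["u", "v"])
        y = rng.standard_normal(10_000)
        fit = mdl.fit_ols(X, y, include_interactions=False)
        assert abs(fit.coefficients["u"]) < 0.05
        assert abs(fit.coefficients["v"]) < 0.05

    def test_rank_deficient_design_rejected(self, rng):
        x = rng.standard_normal(12)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            mdl.fit_ols(X, rng.standard_normal(12), include_interactions=False)

    def test_too_few_rows_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((3, 2)))
        with pytest.raises(ValueError):
            mdl.fit_ols(X, rng.standard_normal(3), include_interactions=True)
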