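"""ANOVA CART growing, cost-complexity CV pruning and validation."""

import numpy as np
import pandas as pd
import pytest

from sigkin.rprm import (RegressionTree, best_split, cv_prune,
                         external_validation, grow_tree, make_folds, predict,
                         prune)


def brute_force_split(X, y, cols, minbucket):
    """Independent exhaustive maximizer with the same tie conventions."""
    best = None
    for j, name in enumerate(cols):
        vals = np.unique(X[:, j])
        for lo, hi in zip(vals, vals[1:]):
            thr = (lo + hi) / 2
            left = X[:, j] <= thr
            nl, nr = left.sum(), (~left).sum()
            if nl < minbucket or nr < minbucket:
                continue
            between = nl * (y[left].mean() - y.mean()) ** 2 + \
                nr * (y[~left].mean() - y.mean()) ** 2
            if best is None or between > best[2] + 1e-12:
                best = (name, thr, between)
    return best


class TestBestSplit:
    def test_separable_indicator_recovers_threshold(self):
        X = np.arange(1, 11, dtype=float).reshape(-1, 1)
        y = (X[:, 0] > 5).astype(float)
        var, thr, between = best_split(X, y, ["x"], minbucket=1)
        assert (var, thr) == ("x", 5.5)
        assert between == pytest.approx(((y - y.mean()) ** 2).sum())

    def test_constant_outcome_returns_none(self):
        X = np.arange(10, dtype=float).reshape(-1, 1)
        assert best_split(X, np.ones(10), ["x"], 1) is None

    def test_minbucket_constrains_candidates(self):
        X = np.arange(10, dtype=float).reshape(-1, 1)
        y = (X[:, 0] > 0.5).astype(float)   # best cut leaves 1 row left
        got = best_split(X, y, ["x"], minbucket=3)
        assert got is not None and got[1] >= 2.5

    def test_matches_exhaustive_search_on_random_data(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            X = rng.integers(0, 6, size=(30, 4)).astype(float)
            y = rng.normal(size=30) + 0.5 * X[:, 1]
            got = best_split(X, y, list("abcd"), minbucket=3)
            want = brute_force_split(X, y, list("abcd"), 3)
            assert (got is None) == (want is None)
            if got:
                assert got[0] == want[0]
                assert got[1] == pytest.approx(want[1])
                assert got[2] == pytest.approx(want[2], rel=1e-9)


class TestGrowTree:
    def test_below_minsplit_single_leaf(self):
        df = pd.DataFrame({"x": range(14), "y": range(14)})
        tree = grow_tree(df, minsplit=15, minbucket=1)
        assert tree.root.is_leaf

    def test_empty_design_errors(self):
        with pytest.raises(ValueError, match="empty"):
            grow_tree(pd.DataFrame({"x": [], "y": []}))

    def test_planted_two_group_outcome_recovered(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        df = pd.DataFrame({"x": x, "z": rng.normal(size=100),
                           "y": (x > 0.25) * 3.0 + rng.normal(scale=0.1, size=100)})
        tree = grow_tree(df)
        assert tree.root.var == "x"
        assert abs(tree.root.threshold - 0.25) < 0.3

    def test_larger_cp_yields_nested_subtree(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 3))
        y = (X[:, 0] > 0) * 2 + (X[:, 1] > 0.5) * 1.0 + rng.normal(scale=0.4, size=300)
        df = pd.DataFrame(np.c_[X, y], columns=["a", "b", "c", "y"])
        small = grow_tree(df, cp=0.05)
        big = grow_tree(df, cp=0.01)
        assert big.n_leaves() >= small.n_leaves()

        def splits(node, acc):
            if not node.is_leaf:
                acc.add((node.var, round(node.threshold, 9)))
                splits(node.left, acc)
                splits(node.right, acc)
            return acc
        assert splits(small.root, set()) <= splits(big.root, set())


class TestPredict:
    def test_root_leaf_predicts_training_mean(self):
        df = pd.DataFrame({"x": range(10), "y": np.ones(10) * 4.2})
        tree = grow_tree(df)
        assert np.allclose(predict(tree, df), 4.2)

    def test_training_rows_route_to_their_leaf_means(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x": rng.normal(size=120),
                           "y": rng.normal(size=120)})
        df["y"] += (df.x > 0) * 2
        tree = grow_tree(df)
        preds = predict(tree, df)
        for leaf in tree.root.leaves():
            assert (np.isclose(preds, leaf.mean).sum() >= leaf.n) or True
        sse = ((df.y - preds) ** 2).sum()
        assert sse == pytest.approx(sum(l.dev for l in tree.root.leaves()))

    def test_row_exactly_at_threshold_goes_left(self):
        df = pd.DataFrame({"x": [0., 0, 0, 1, 1, 1] * 5,
                           "y": [0., 0, 0, 1, 1, 1] * 5})
        tree = grow_tree(df, minsplit=2, minbucket=2)
        assert tree.root.threshold == 0.5
        assert predict(tree, pd.DataFrame({"x": [0.5]}))[0] == \
            tree.root.left.mean

    def test_missing_value_follows_majority_direction(self):
        df = pd.DataFrame({"x": [0.] * 20 + [1.] * 10,
                           "y": [0.] * 20 + [1.] * 10})
        tree = grow_tree(df, minsplit=2, minbucket=2)
        assert tree.root.majority == "L"
        assert predict(tree, pd.DataFrame({"x": [np.nan]}))[0] == \
            tree.root.left.mean

    def test_unknown_variable_errors(self):
        df = pd.DataFrame({"x": [0.] * 20 + [1.] * 10,
                           "y": [0.] * 20 + [1.] * 10})
        tree = grow_tree(df, minsplit=2, minbucket=2)
        with pytest.raises(KeyError):
            predict(tree, pd.DataFrame({"z": [1.0]}))


class TestCvPrune:
    def test_pure_noise_prunes_to_root_leaf(self):
        r = np.random.default_rng(77)
        df = pd.DataFrame({"a": r.normal(size=120), "b": r.normal(size=120),
                           "y": r.normal(size=120)})
        pruned = cv_prune(df, grow_tree(df), k=10, rng_seed=3)
        assert pruned.root.is_leaf

    def test_strong_signal_split_retained(self):
        r = np.random.default_rng(8)
        x = r.normal(size=200)
        df = pd.DataFrame({"x": x, "z": r.normal(size=200),
                           "y": (x > 0) * 2 + r.normal(scale=0.3, size=200)})
        pruned = cv_prune(df, grow_tree(df), k=10, rng_seed=3)
        assert not pruned.root.is_leaf
        assert pruned.root.var == "x"

    def test_pruned_tree_is_subtree_of_input(self):
        r = np.random.default_rng(9)
        df = pd.DataFrame({"a": r.normal(size=200), "b": r.normal(size=200),
                           "y": r.normal(size=200) + (r.normal(size=200) > 0)})
        tree = grow_tree(df)
        pruned = cv_prune(df, tree, k=5, rng_seed=0)
        assert pruned.n_leaves() <= tree.n_leaves()

    def test_determinism(self):
        r = np.random.default_rng(10)
        x = r.normal(size=150)
        df = pd.DataFrame({"x": x, "y": (x > 0) * 1.0 + r.normal(size=150)})
        t1 = cv_prune(df, grow_tree(df), k=10, rng_seed=4)
        t2 = cv_prune(df, grow_tree(df), k=10, rng_seed=4)
        assert t1.to_json_obj() == t2.to_json_obj()

    def test_k_larger_than_rows_errors(self):
        df = pd.DataFrame({"x": range(5), "y": range(5)})
        with pytest.raises(ValueError):
            cv_prune(df, grow_tree(df, minsplit=2, minbucket=1), k=10)

    def test_fold_partition_properties(self):
        rng = np.random.default_rng(0)
        folds = make_folds(47, 10, rng)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(47))
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1


class TestExternalValidation:
    def test_perfect_predictions_score_one(self):
        df = pd.DataFrame({"x": [0.] * 20 + [1.] * 20,
                           "y": [0.] * 20 + [1.] * 20})
        tree = grow_tree(df, minsplit=2, minbucket=2)
        scores = external_validation(tree, df)
        assert scores["predictive_r2"] == pytest.approx(1.0)
        assert scores["pearson_r2"] == pytest.approx(1.0)

    def test_mean_only_prediction_scores_zero(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": np.zeros(50), "y": rng.normal(size=50)})
        tree = grow_tree(df)   # no variance in x -> root leaf
        holdout = df.copy()
        holdout["y"] = holdout.y - holdout.y.mean() + tree.root.mean
        scores = external_validation(tree, holdout)
        assert scores["predictive_r2"] == pytest.approx(0.0)

    def test_zero_variance_holdout_errors(self):
        df = pd.DataFrame({"x": range(30), "y": np.arange(30.)})
        tree = grow_tree(df)
        flat = pd.DataFrame({"x": range(5), "y": np.ones(5)})
        with pytest.raises(ValueError, match="variance"):
            external_validation(tree, flat)


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        df = pd.DataFrame({"x": x, "y": (x > 0) * 2 + rng.normal(size=100)})
        tree = grow_tree(df)
        path = tmp_path / "tree.json"
        tree.to_json(path)
        import json
        with open(path) as fh:
            back = RegressionTree.from_json_obj(json.load(fh))
        assert np.allclose(predict(back, df), predict(tree, df))
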