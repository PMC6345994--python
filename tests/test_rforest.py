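"""Split-rule random forest: entropy, candidate proposal, training, prediction."""

import numpy as np
import pytest

from hyperclass import (
    ForestConfig,
    ForestModel,
    SplitRule,
    best_split,
    entropy,
    forest_predict,
    predict_proba,
    propose_candidates,
    train_forest,
    train_tree,
)
from hyperclass.rforest import DIFFERENCE, SINGLE, TreeNode, tree_depth


class TestEntropy:
    @pytest.mark.parametrize(
        "labels,expected",
        [
            ([1, 1, 1, 1], 0.0),
            ([0, 0, 1, 1], 1.0),
            ([0, 1, 2, 3], 2.0),
            ([0, 0, 0, 1], -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))),
        ],
        ids=["pure", "fifty-fifty", "four-way-uniform", "three-one"],
    )
    def test_known_values_in_bits(self, labels, expected):
        assert entropy(np.asarray(labels)) == pytest.approx(expected)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            entropy(np.array([]))


class TestProposeCandidates:
    def test_thresholds_lie_in_node_range(self, rng):
        X = rng.normal(size=(30, 4))
        rules = propose_candidates(X, None, 200, rng)
        assert len(rules) == 200
        for r in rules:
            e = r.expression(X)
            assert e.min() <= r.threshold <= e.max()

    def test_single_feature_prevents_difference_rules(self, rng):
        rules = propose_candidates(rng.normal(size=(20, 1)), None, 100, rng)
        assert all(r.rule_type == SINGLE for r in rules)

    def test_difference_rules_use_distinct_features(self, rng):
        rules = propose_candidates(rng.normal(size=(20, 5)), None, 300, rng)
        assert any(r.rule_type == DIFFERENCE for r in rules)
        for r in rules:
            if r.rule_type == DIFFERENCE:
                assert r.i != r.j

    def test_fixed_seed_reproduces_candidates(self, rng):
        X = rng.normal(size=(25, 3))
        a = propose_candidates(X, None, 50, np.random.default_rng(9))
        b = propose_candidates(X, None, 50, np.random.default_rng(9))
        assert a == b

    def test_degenerate_node_yields_empty_list(self, rng):
        assert propose_candidates(np.ones((10, 3)), None, 50, rng) == []


class TestBestSplit:
    def test_perfect_1d_split_gains_one_bit(self):
        """Exhaustive oracle: on [0,1,2,3] labelled AABB every threshold in
        [1, 2) separates perfectly for a gain of exactly 1 bit."""
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        gains = {}
        for thr in np.linspace(-0.5, 3.5, 81):
            left = y[X[:, 0] <= thr]
            right = y[X[:, 0] > thr]
            if len(left) == 0 or len(right) == 0:
                continue
            gains[thr] = entropy(y) - (
                len(left) * entropy(left) + len(right) * entropy(right)
            ) / len(y)
        assert max(gains.values()) == pytest.approx(1.0)
        rule, gain = best_split(X, y, [SplitRule(SINGLE, 0, None, 1.5)])
        assert gain == pytest.approx(1.0)
        assert rule.threshold == 1.5

    def test_identical_labels_give_none(self, rng):
        X = rng.normal(size=(10, 2))
        assert best_split(X, np.zeros(10, dtype=int),
                          [SplitRule(SINGLE, 0, None, 0.0)]) is None

    def test_difference_rule_beats_axis_aligned_on_oblique_labels(self, rng):
        """Labels = sign(f1 - f2): one difference rule is a perfect 1-bit
        split while every axis-aligned threshold falls short (checked
        exhaustively over all sample-interval thresholds)."""
        X = rng.uniform(size=(20, 2))
        y = (X[:, 0] - X[:, 1] > 0).astype(int)
        axis_best = 0.0
        for f in (0, 1):
            for thr in np.sort(X[:, f])[:-1] + np.diff(np.sort(X[:, f])) / 2:
                res = best_split(X, y, [SplitRule(SINGLE, f, None, float(thr))])
                if res is not None:
                    axis_best = max(axis_best, res[1])
        oblique = best_split(X, y, [SplitRule(DIFFERENCE, 0, 1, 0.0)])
        # a perfect split recovers the full parent entropy as gain
        assert oblique[1] == pytest.approx(entropy(y))
        assert axis_best < oblique[1]

    def test_equal_gain_ties_go_to_first_candidate(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        first = SplitRule(SINGLE, 0, None, 1.2)
        second = SplitRule(SINGLE, 0, None, 1.8)
        rule, _ = best_split(X, y, [first, second])
        assert rule is first


class TestTrainTree:
    def test_separable_data_reaches_perfect_training_accuracy(self, rng):
        X = np.concatenate([rng.normal(-3, 0.3, (40, 2)), rng.normal(3, 0.3, (40, 2))])
        y = np.repeat([0, 1], 40)
        tree = train_tree(X, y, ForestConfig(n_trees=1, seed=0), np.random.default_rng(0))
        model = ForestModel([tree], ForestConfig(n_trees=1), (0, 1))
        acc = (forest_predict(model, X.astype(np.float32)) == y).mean()
        assert acc == 1.0

    def test_max_depth_zero_gives_prior_leaf(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.array([0] * 20 + [1] * 10)
        tree = train_tree(X, y, ForestConfig(max_depth=0), np.random.default_rng(0))
        assert tree.is_leaf
        np.testing.assert_allclose(tree.class_probs, [2 / 3, 1 / 3])

    def test_pure_input_gives_certain_leaf(self, rng):
        tree = train_tree(rng.normal(size=(15, 2)), np.ones(15, dtype=int),
                          ForestConfig(), np.random.default_rng(0), classes=(0, 1))
        assert tree.is_leaf
        np.testing.assert_allclose(tree.class_probs, [0.0, 1.0])

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_tree(np.zeros((0, 2)), np.zeros(0), ForestConfig(),
                       np.random.default_rng(0))

    def test_node_class_counts_conserved_and_gains_positive(self, rng):
        """Walking any trained tree, parent sample counts equal the sum of
        the children's, and every executed split strictly reduced entropy."""
        X = rng.normal(size=(200, 4)).astype(np.float32)
        y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(int)
        tree = train_tree(X, y, ForestConfig(max_depth=6), np.random.default_rng(2))

        def walk(node, Xn, yn):
            if node.is_leaf:
                np.testing.assert_allclose(
                    node.class_probs, np.bincount(yn, minlength=2) / yn.size
                )
                return
            e = node.rule.expression(Xn)
            m = e <= node.rule.threshold
            assert 0 < m.sum() < yn.size
            h_parent = entropy(yn)
            h_split = (m.sum() * entropy(yn[m]) + (~m).sum() * entropy(yn[~m])) / yn.size
            assert h_parent - h_split > 0
            walk(node.left, Xn[m], yn[m])
            walk(node.right, Xn[~m], yn[~m])

        walk(tree, X, y)


class TestForest:
    def _toy(self, rng, n=300):
        X = rng.normal(size=(n, 3)).astype(np.float32)
        y = np.where(X[:, 0] > 0, 1, 0).astype(np.uint8)
        return X, y

    def test_identical_seeds_serialize_byte_identically(self, rng):
        X, y = self._toy(rng)
        cfg = ForestConfig(n_trees=5, max_depth=6, n_candidates=50, seed=7)
        a = train_forest([X], [y], cfg, classes=(0, 1))
        b = train_forest([X], [y], cfg, classes=(0, 1))
        assert a.to_json() == b.to_json()

    def test_serialization_round_trip_preserves_predictions(self, rng):
        X, y = self._toy(rng)
        cfg = ForestConfig(n_trees=3, max_depth=5, n_candidates=50, seed=1)
        model = train_forest([X], [y], cfg, classes=(0, 1))
        back = ForestModel.from_json(model.to_json())
        np.testing.assert_array_equal(
            forest_predict(model, X), forest_predict(back, X)
        )

    def test_missing_class_raises_with_class_listed(self, rng):
        X = rng.normal(size=(50, 2)).astype(np.float32)
        y = np.zeros(50, dtype=np.uint8)
        with pytest.raises(ValueError, match="absent.*\\[1, 2, 3\\]"):
            train_forest([X], [y], ForestConfig(n_trees=2))

    def test_ignore_pixels_excluded_from_training(self, rng):
        X = rng.normal(size=(100, 2)).astype(np.float32)
        y = np.where(X[:, 0] > 0, 1, 0).astype(np.uint8)
        y_with_ignore = y.copy()
        y_with_ignore[:30] = 255
        cfg = ForestConfig(n_trees=3, max_depth=4, n_candidates=50, seed=0)
        a = train_forest([X], [y_with_ignore], cfg, classes=(0, 1))
        b = train_forest([X[30:]], [y[30:]], cfg, classes=(0, 1))
        assert a.to_json() == b.to_json()

    def test_probabilities_sum_to_one_and_average_trees(self, rng):
        X, y = self._toy(rng)
        model = train_forest(
            [X], [y], ForestConfig(n_trees=4, max_depth=4, n_candidates=50, seed=3),
            classes=(0, 1),
        )
        proba = predict_proba(model, X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        single = np.mean(
            [predict_proba(ForestModel([t], model.config, model.classes), X)
             for t in model.trees],
            axis=0,
        )
        np.testing.assert_allclose(proba, single, atol=1e-12)

    def test_two_leaf_average_and_argmax_tie_rule(self):
        cfg = ForestConfig(n_trees=2)
        t1 = TreeNode(class_probs=np.array([1.0, 0.0]))
        t2 = TreeNode(class_probs=np.array([0.0, 1.0]))
        model = ForestModel([t1, t2], cfg, (0, 1))
        X = np.zeros((3, 2), dtype=np.float32)
        np.testing.assert_allclose(predict_proba(model, X), 0.5)
        # exact tie resolves to the lowest class code
        np.testing.assert_array_equal(forest_predict(model, X), 0)

    def test_argmax_agrees_with_proba_everywhere(self, rng):
        X, y = self._toy(rng)
        model = train_forest(
            [X], [y], ForestConfig(n_trees=3, max_depth=5, n_candidates=50, seed=2),
            classes=(0, 1),
        )
        proba = predict_proba(model, X)
        np.testing.assert_array_equal(
            forest_predict(model, X), np.argmax(proba, axis=1)
        )

    def test_depth_limit_respected(self, rng):
        X = rng.normal(size=(500, 2)).astype(np.float32)
        y = rng.integers(0, 2, 500).astype(np.uint8)  # unlearnable noise
        model = train_forest(
            [X], [y], ForestConfig(n_trees=2, max_depth=4, n_candidates=30, seed=0),
            classes=(0, 1),
        )
        assert all(tree_depth(t) <= 4 for t in model.trees)

    def test_oblique_rules_solve_difference_boundary_shallow_trees(self, rng):
        """On labels = sign(f_i - f_j), difference rules reach near-perfect
        training accuracy with depth-3 trees while an axis-aligned-only
        forest of the same budget cannot."""
        X = rng.uniform(size=(2000, 2)).astype(np.float32)
        y = (X[:, 0] - X[:, 1] > 0).astype(np.uint8)
        kw = dict(n_trees=10, max_depth=3, n_candidates=400, seed=5)
        oblique = train_forest([X], [y], ForestConfig(**kw), classes=(0, 1))
        axis = train_forest(
            [X], [y], ForestConfig(rule_types=(SINGLE,), **kw), classes=(0, 1)
        )
        acc_oblique = (forest_predict(oblique, X) == y).mean()
        acc_axis = (forest_predict(axis, X) == y).mean()
        assert acc_oblique >= 0.98
        assert acc_axis < 0.98

    def test_feature_count_mismatch_raises(self, rng):
        X, y = self._toy(rng)
        from hyperclass.morphfeat import FeatureStack

        fs = FeatureStack(planes=X.T.reshape(3, 30, 10), names=("a", "b", "c"))
        model = train_forest([fs], [y.reshape(30, 10)],
                             ForestConfig(n_trees=2, max_depth=3, n_candidates=30),
                             classes=(0, 1))
        with pytest.raises(ValueError, match="feature count"):
            predict_proba(model, np.zeros((5, 7), dtype=np.float32))
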