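"""MI-redundancy grouping, representative selection, and weighted voting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from miforest import (
    Forest,
    IRFModel,
    accuracy_matrix,
    fit_irf,
    group_trees,
    select_representatives,
    train_forest,
    weight_matrix,
)


def symmetric_matrix(t, rng):
    M = rng.uniform(0, 2, size=(t, t))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 2.0)
    return M


class TestGroupTrees:
    def _example_matrix(self):
        # trees 0-1 redundant (0.9), trees 2-3 redundant (0.8), cross pairs 0.05
        M = np.full((4, 4), 0.05)
        M[0, 1] = M[1, 0] = 0.9
        M[2, 3] = M[3, 2] = 0.8
        np.fill_diagonal(M, 1.0)
        return M

    def test_hand_traced_grouping(self):
        g = group_trees(self._example_matrix(), 0.5)
        assert g.groups == [[0, 1], [2, 3]]

    def test_epsilon_above_max_gives_all_singletons(self):
        g = group_trees(self._example_matrix(), 0.95)
        assert g.groups == [[0], [1], [2], [3]]

    def test_epsilon_zero_with_positive_mi_gives_one_group(self):
        g = group_trees(self._example_matrix(), 0.0)
        assert g.groups == [[0, 1, 2, 3]]

    def test_negative_epsilon_is_error(self):
        with pytest.raises(ValueError):
            group_trees(np.eye(3), -0.1)

    @given(st.integers(2, 12), st.integers(0, 10_000), st.floats(0, 2), st.floats(0, 2))
    @settings(deadline=None, max_examples=60)
    def test_partition_and_monotonicity(self, t, seed, eps1, eps2):
        M = symmetric_matrix(t, np.random.default_rng(seed))
        lo, hi = sorted((eps1, eps2))
        g_lo, g_hi = group_trees(M, lo), group_trees(M, hi)
        for g in (g_lo, g_hi):
            flat = sorted(i for grp in g.groups for i in grp)
            assert flat == list(range(t))  # disjoint cover
        # stricter absorption never merges more
        assert g_hi.n_groups >= g_lo.n_groups


class TestSelectRepresentatives:
    def test_all_singletons_keep_everything(self):
        g = group_trees(np.eye(3), 0.5)
        assert select_representatives(g, np.array([0.1, 0.2, 0.3])) == [0, 1, 2]

    def test_highest_truth_mi_wins(self):
        g = group_trees(np.array([[1, 0.9], [0.9, 1]]), 0.5)
        assert g.groups == [[0, 1]]
        assert select_representatives(g, np.array([0.30, 0.70])) == [1]

    def test_tie_keeps_smallest_index(self):
        g = group_trees(np.array([[1, 0.9], [0.9, 1]]), 0.5)
        assert select_representatives(g, np.array([0.5, 0.5])) == [0]


class TestAccuracyAndWeights:
    def test_per_class_recall_example(self, easy_split):
        # validate the a_gc definition directly against hand counts
        truth = np.array([0, 0, 1, 1, 2, 2])
        pred = np.array([0, 1, 1, 1, 2, 0])
        col = [
            (pred[truth == g] == g).mean() for g in range(3)
        ]
        assert col == [0.5, 1.0, 0.5]
        # and accuracy_matrix computes exactly this per kept tree
        train, _ = easy_split
        forest = train_forest(train, n_trees=3, seed=0)
        val = train.subset(np.arange(30))
        A = accuracy_matrix(forest, val)
        votes = forest.predict_matrix(val.features)
        for c in range(3):
            for g in range(val.n_classes):
                in_g = val.labels == g
                assert A[g, c] == pytest.approx((votes[c, in_g] == g).mean())

    def test_weight_matrix_is_identity_mapping(self):
        A = np.array([[1.0, 0.75], [0.0, 0.5]])
        Q = weight_matrix(A)
        assert np.array_equal(Q, A)
        Q[0, 0] = 0.0  # returned copy must not alias A
        assert A[0, 0] == 1.0

    def test_out_of_range_accuracy_is_error(self):
        with pytest.raises(ValueError):
            weight_matrix(np.array([[1.2]]))

    def test_missing_validation_class_zeroes_row(self, easy_split, caplog):
        train, _ = easy_split
        forest = train_forest(train, n_trees=2, seed=0)
        val = train.subset(np.flatnonzero(train.labels != 3))
        with caplog.at_level("WARNING", logger="miforest.irf_ensemble"):
            A = accuracy_matrix(forest, val)
        assert np.all(A[3] == 0.0)
        assert any("no samples" in r.message for r in caplog.records)


class TestWeightedVote:
    def _two_tree_model(self, easy_split):
        train, _ = easy_split
        forest = train_forest(train, n_trees=2, seed=0)
        return forest

    def test_asymmetric_weights_override_tie(self):
        # 2 trees voting (0, 1); weight of tree 1 for class 0 dominates
        from miforest.cart_tree import DecisionTree, Leaf

        t0 = DecisionTree(Leaf(0, np.array([1, 0])), 1, 2, 1)
        t1 = DecisionTree(Leaf(1, np.array([0, 1])), 1, 2, 1)
        forest = Forest([t0, t1], 1, 1, 0, ["a", "b"], ["x"])
        Q = np.array([[0.9, 0.0], [0.0, 0.4]])
        model = IRFModel(forest, Q, Q.copy(), ["a", "b"], 0.1)
        assert model.predict_one([0.0]) == 0  # score(0)=0.9 > score(1)=0.4

    def test_unit_weights_reduce_to_majority_vote(self, easy_split):
        train, test = easy_split
        forest = train_forest(train, n_trees=9, seed=3)
        Q = np.ones((train.n_classes, forest.n_trees))
        model = IRFModel(forest, Q, Q.copy(), train.class_names, 0.0)
        assert np.array_equal(
            model.predict(test.features), forest.predict(test.features)
        )

    def test_single_tree_model_echoes_the_tree(self, easy_split):
        train, test = easy_split
        forest = train_forest(train, n_trees=1, seed=3)
        Q = np.ones((train.n_classes, 1))
        model = IRFModel(forest, Q, Q.copy(), train.class_names, 0.0)
        assert np.array_equal(
            model.predict(test.features), forest.trees[0].predict(test.features)
        )

    def test_all_zero_weights_fall_back_to_majority(self, easy_split):
        train, test = easy_split
        forest = train_forest(train, n_trees=3, seed=3)
        Q = np.zeros((train.n_classes, 3))
        model = IRFModel(forest, Q, Q.copy(), train.class_names, 0.0)
        with pytest.warns(UserWarning, match="fell back"):
            pred = model.predict(test.features[:5])
        assert np.array_equal(pred, forest.predict(test.features[:5]))


class TestFitIRF:
    def test_duplicated_trees_collapse_to_one(self, easy_split):
        train, test = easy_split
        rng = np.random.default_rng(0)
        tr, val = train.stratified_split(0.75, rng)
        base = train_forest(tr, n_trees=4, seed=6)
        dup = Forest(
            [base.trees[0], base.trees[0]] + base.trees[1:],
            base.bootstrap_n, base.d, base.seed, base.class_names, base.feature_names,
        )
        model = fit_irf(tr, val, forest=dup, epsilon=0.5)
        sizes = model.fit_report["group_sizes"]
        assert max(sizes) >= 2  # the duplicates share a group
        kept = model.fit_report["kept_indices"]
        assert not (0 in kept and 1 in kept)  # exactly one duplicate survives

    def test_epsilon_above_max_keeps_whole_forest(self, easy_split):
        train, _ = easy_split
        rng = np.random.default_rng(1)
        tr, val = train.stratified_split(0.75, rng)
        model = fit_irf(tr, val, n_trees=8, seed=2, epsilon=1e6)
        assert model.pruned_forest.n_trees == 8
        assert model.fit_report["kept_indices"] == list(range(8))

    def test_deterministic_serialization(self, easy_split):
        train, _ = easy_split
        rng1, rng2 = np.random.default_rng(2), np.random.default_rng(2)
        tr1, val1 = train.stratified_split(0.75, rng1)
        tr2, val2 = train.stratified_split(0.75, rng2)
        m1 = fit_irf(tr1, val1, n_trees=6, seed=9)
        m2 = fit_irf(tr2, val2, n_trees=6, seed=9)
        assert m1.to_dict() == m2.to_dict()

    def test_single_class_train_is_error(self, easy_split):
        train, _ = easy_split
        only0 = train.subset(np.flatnonzero(train.labels == 0))
        with pytest.raises(ValueError):
            fit_irf(only0, train, n_trees=3, seed=0)

    def test_holdout_accuracy_on_separated_classes(self, easy_split):
        train, test = easy_split
        rng = np.random.default_rng(3)
        tr, val = train.stratified_split(0.75, rng)
        model = fit_irf(tr, val, n_trees=50, seed=1)
        acc = (model.predict(test.features) == test.labels).mean()
        assert acc >= 0.95

    def test_json_round_trip_preserves_predictions(self, easy_split, tmp_path):
        train, test = easy_split
        rng = np.random.default_rng(4)
        tr, val = train.stratified_split(0.75, rng)
        model = fit_irf(tr, val, n_trees=10, seed=5)
        path = tmp_path / "model.json"
        model.to_json(path)
        clone = IRFModel.from_json(path)
        assert np.array_equal(
            model.predict(test.features), clone.predict(test.features)
        )
        assert np.array_equal(model.weight_matrix, clone.weight_matrix)
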