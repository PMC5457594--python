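"""CART growth, split selection (vs brute-force oracle) and CV depth search."""

import numpy as np
import pytest

from ntacpred.cart import (DecisionTree, TrainConfig, TreeNode,
                           cross_validate_depth, find_best_split, fit_predictor,
                           gini_impurity, grow_tree, grow_tree_root)
from ntacpred.encoding import WindowSpec, encode_dataset, encode_window, feature_index
from ntacpred.seqdata import LabeledSequence, SequenceDataset


def brute_force_best_split(X, y):
    """Independent oracle: exhaustive exact-rational scan of every feature.

    Returns (feature, float decrease) for the lowest-index feature with the
    strictly largest Gini decrease, or None when no split helps.
    """
    from fractions import Fraction

    n = len(y)
    n_pos = int(y.sum())
    if n_pos in (0, n):
        return None

    def gini_frac(p, m):
        return Fraction(1) - Fraction(p, m) ** 2 - Fraction(m - p, m) ** 2

    parent = gini_frac(n_pos, n)
    best = None
    for f in range(X.shape[1]):
        m = X[:, f] == 1
        ny, nn = int(m.sum()), int((~m).sum())
        if ny == 0 or nn == 0:
            continue
        py, pn = int(y[m].sum()), int(y[~m].sum())
        dec = parent - (Fraction(ny) * gini_frac(py, ny)
                        + Fraction(nn) * gini_frac(pn, nn)) / n
        if dec > 0 and (best is None or dec > best[1]):
            best = (f, dec)
    return (best[0], float(best[1])) if best else None


def encode_cases(rows):
    """rows: list of (window, label 0/1) -> (X, y)."""
    X = np.stack([encode_window(w) for w, _ in rows])
    y = np.array([l for _, l in rows], dtype=np.int8)
    return X, y


class TestGini:
    def test_pure_node_is_zero(self):
        assert gini_impurity(10, 0) == 0.0
        assert gini_impurity(0, 7) == 0.0

    def test_balanced_node_is_half(self):
        assert gini_impurity(5, 5) == 0.5

    def test_direct_evaluation(self):
        assert gini_impurity(3, 1) == pytest.approx(0.375)  # 1 - 9/16 - 1/16

    def test_empty_node_errors(self):
        with pytest.raises(ValueError):
            gini_impurity(0, 0)


class TestFindBestSplit:
    def test_perfect_separator_found(self):
        rows = [("SAA", 1)] * 4 + [("GAA", 0)] * 4
        X, y = encode_cases(rows)
        f, dec = find_best_split(X, y)
        assert f == feature_index(1, "G")  # ties S/G broken to lower index (G < S)
        assert dec == pytest.approx(0.5)

    def test_pure_set_returns_none(self):
        X, y = encode_cases([("SAA", 1), ("GAA", 1)])
        assert find_best_split(X, y) is None

    def test_tie_broken_to_lowest_feature_index(self):
        # 1:A, 1:C, 2:A and 2:D all separate perfectly; 1:A has the lowest
        # (position-major, alphabet-rank-minor) feature index
        rows = [("CDA", 1), ("CDA", 1), ("AAA", 0), ("AAA", 0)]
        X, y = encode_cases(rows)
        f, _ = find_best_split(X, y)
        assert f == feature_index(1, "A")

    def test_exactly_tied_gains_resolved_consistently(self):
        # 1:A and 1:S give mathematically identical decreases (1/24); the
        # lower index (A) must win regardless of float evaluation order
        rows = [("D", 1), ("D", 0), ("S", 1), ("D", 1),
                ("A", 1), ("S", 1), ("D", 1), ("A", 0)]
        X, y = encode_cases(rows)
        f, dec = find_best_split(X, y)
        assert f == feature_index(1, "A")
        assert dec == pytest.approx(1 / 24)

    def test_no_positive_gain_returns_none(self):
        # every feature splits 1:1 with one of each class in each child
        rows = [("AC", 1), ("CA", 1), ("AC", 0), ("CA", 0)]
        X, y = encode_cases(rows)
        assert find_best_split(X, y) is None

    def test_matches_oracle_on_random_tiny_datasets(self):
        """Sweep ≤8-case × ≤3-position datasets on a 3-letter alphabet."""
        rng = np.random.default_rng(123)
        letters = "ASD"
        for _ in range(300):
            n = int(rng.integers(2, 9))
            L = int(rng.integers(1, 4))
            rows = [("".join(rng.choice(list(letters), L)), int(rng.integers(2)))
                    for _ in range(n)]
            X, y = encode_cases(rows)
            got = find_best_split(X, y)
            want = brute_force_best_split(X, y)
            if want is None:
                assert got is None
            else:
                assert got is not None
                assert got[0] == want[0]
                assert got[1] == pytest.approx(want[1])

    def test_matches_oracle_on_all_label_assignments(self):
        """Exhaustive enumeration over every labeling of a fixed case set."""
        windows = ["SA", "SD", "AS", "AD", "DS", "DA"]
        for mask in range(2 ** len(windows)):
            rows = [(w, (mask >> i) & 1) for i, w in enumerate(windows)]
            X, y = encode_cases(rows)
            got = find_best_split(X, y)
            want = brute_force_best_split(X, y)
            if want is None:
                assert got is None
            else:
                assert got[0] == want[0] and got[1] == pytest.approx(want[1])


class TestGrowTree:
    def test_pure_set_yields_single_leaf(self):
        X, y = encode_cases([("SAA", 1), ("SDA", 1)])
        root = grow_tree_root(X, y, max_depth=5)
        assert root.is_leaf and root.depth() == 0

    def test_planted_rule_recovered_at_depth_one(self):
        rows = [("ACD", 1)] * 5 + [("CAD", 0)] * 3 + [("DDA", 0)] * 3
        X, y = encode_cases(rows)
        root = grow_tree_root(X, y, max_depth=5)
        assert root.feature == feature_index(1, "A")
        assert root.depth() == 1

    def test_max_depth_bound_enforced(self, study_ds):
        X, y = encode_dataset(study_ds, WindowSpec(10, 1))
        root = grow_tree_root(X[:100], y[:100], max_depth=1)
        assert root.depth() <= 1

    def test_child_counts_sum_to_parent(self, study_ds):
        X, y = encode_dataset(study_ds, WindowSpec(10, 1))
        root = grow_tree_root(X, y, max_depth=6)

        def check(node):
            if node.is_leaf:
                return
            assert node.yes.n + node.no.n == node.n
            assert node.yes.n_pos + node.no.n_pos == node.n_pos
            check(node.yes)
            check(node.no)

        check(root)

    def test_impurity_nonincreasing_down_every_path(self, study_ds):
        X, y = encode_dataset(study_ds, WindowSpec(10, 1))
        root = grow_tree_root(X, y, max_depth=8)

        def check(node):
            if node.is_leaf:
                return
            parent = gini_impurity(node.n_pos, node.n_neg)
            w = (node.yes.n * gini_impurity(node.yes.n_pos, node.yes.n_neg)
                 + node.no.n * gini_impurity(node.no.n_pos, node.no.n_neg)) / node.n
            assert w < parent + 1e-12
            check(node.yes)
            check(node.no)

        check(root)

    def test_deeper_trees_never_increase_training_error(self, study_ds):
        X, y = encode_dataset(study_ds, WindowSpec(10, 1))
        from ntacpred.cart import _predict_encoded

        errors = []
        for depth in (1, 2, 4, 6, 8, 10):
            root = grow_tree_root(X, y, depth)
            errors.append(int((_predict_encoded(root, X) != y).sum()))
        assert errors == sorted(errors, reverse=True) or all(
            a >= b for a, b in zip(errors, errors[1:]))

    def test_determinism(self, study_ds):
        t1 = grow_tree(study_ds, 6)
        t2 = grow_tree(study_ds, 6)
        assert t1.to_dict() == t2.to_dict()

    def test_root_split_agrees_with_sklearn(self, study_ds):
        """scikit-learn's CART (reference oracle) picks the same root feature."""
        sklearn = pytest.importorskip("sklearn.tree")
        X, y = encode_dataset(study_ds, WindowSpec(10, 1))
        sk = sklearn.DecisionTreeClassifier(max_depth=3, random_state=0).fit(X, y)
        root = grow_tree_root(X, y, 3)
        assert root.feature == sk.tree_.feature[0]


class TestPredict:
    def hand_tree(self):
        # pos1 = S ? -> Ac, else unAc
        root = TreeNode(n_pos=5, n_neg=5, feature=feature_index(1, "S"),
                        yes=TreeNode(n_pos=5, n_neg=0), no=TreeNode(n_pos=0, n_neg=5))
        return DecisionTree(root=root, max_depth=1, window_spec=WindowSpec(10, 1))

    def test_manual_traversal(self):
        t = self.hand_tree()
        assert t.predict_one("SDAAVAKLID") == "positive"
        assert t.predict_one("GDAAVAKLID") == "negative"

    def test_constant_tree(self):
        t = DecisionTree(root=TreeNode(n_pos=3, n_neg=1), max_depth=0)
        assert t.predict(["SDAAVAKLID", "GGGG"]) == ["positive", "positive"]

    def test_leaf_tie_predicts_negative(self):
        assert TreeNode(n_pos=2, n_neg=2).predicted_label == "negative"

    def test_invalid_residue_errors(self):
        from ntacpred.seqdata import DataError

        with pytest.raises(DataError):
            self.hand_tree().predict_one("SDZ")

    def test_serialization_round_trip(self, tmp_path, study_ds):
        t = grow_tree(study_ds, 5)
        f = tmp_path / "tree.json"
        t.save(f)
        back = DecisionTree.load(f)
        assert back.to_dict() == t.to_dict()
        seqs = [r.nterm for r in study_ds][:50]
        assert back.predict(seqs) == t.predict(seqs)


class TestCrossValidation:
    def test_separable_data_selects_smallest_depth(self):
        rows = ([LabeledSequence(f"p{i}", "SAAAAAAAAA", "positive") for i in range(20)]
                + [LabeledSequence(f"n{i}", "GAAAAAAAAA", "negative") for i in range(20)])
        ds = SequenceDataset(rows)
        best, table = cross_validate_depth(ds, TrainConfig(seed=0), WindowSpec(10, 1))
        assert best == 2  # all depths tie at the perfect score
        assert np.allclose(table["mean"], table["mean"].iloc[0])

    def test_singleton_grid(self, study_ds):
        best, table = cross_validate_depth(
            study_ds, TrainConfig(depth_grid=(3,), seed=0), WindowSpec(10, 1))
        assert best == 3 and len(table) == 1

    def test_same_seed_identical_table(self, study_ds):
        cfg = TrainConfig(seed=5)
        _, t1 = cross_validate_depth(study_ds, cfg, WindowSpec(10, 1))
        _, t2 = cross_validate_depth(study_ds, cfg, WindowSpec(10, 1))
        assert t1.equals(t2)

    def test_single_class_errors(self):
        ds = SequenceDataset([LabeledSequence(f"p{i}", "SAAAAAAAAA", "positive")
                              for i in range(30)])
        with pytest.raises(ValueError):
            cross_validate_depth(ds, TrainConfig(), WindowSpec(10, 1))

    def test_fit_predictor_end_to_end(self, study_ds):
        tree = fit_predictor(study_ds, TrainConfig(seed=0))
        assert tree.depth() <= 10
        preds = set(tree.predict([r.nterm for r in study_ds]))
        assert preds == {"positive", "negative"}

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(depth_grid=())
        with pytest.raises(ValueError):
            TrainConfig(n_folds=1)
        with pytest.raises(ValueError):
            TrainConfig(selection_metric="AUC")
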