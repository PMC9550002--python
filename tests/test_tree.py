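import math

import numpy as np
import pytest

from treestrat.errors import EstimationError
from treestrat.tree import (
    CandidateModel,
    Node,
    StratificationTree,
    assign_strata,
    cost_complexity_path,
    cv_prune,
    encode_confounders,
    grow_tree,
    pairwise_node_effects,
    select_model,
    tree_aic,
)

from conftest import make_cohort


def exhaustive_best_split(X, y, min_leaf=7):
    """Independent oracle: evaluate every single split by direct SSE sums."""
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    parent = y.sum() - y.sum() ** 2 / n
    best_j, best_gain = None, 0.0
    for j in range(p):
        mask = X[:, j]
        n1, n0 = mask.sum(), n - mask.sum()
        if n1 < min_leaf or n0 < min_leaf:
            continue
        s1, s0 = y[mask].sum(), y[~mask].sum()
        child = (s1 - s1**2 / n1) + (s0 - s0**2 / n0)
        gain = parent - child
        if gain > best_gain + 1e-12:
            best_j, best_gain = j, gain
    return best_j


def leaf_tree(n, events):
    t = StratificationTree(root=Node(n, events), feature_names=[])
    t.assign_ids()
    return t


def manual_split_tree(feature_name, left, right):
    """Tree with one split; left/right are (n, events)."""
    root = Node(left[0] + right[0], left[1] + right[1])
    root.feature = 0
    root.left = Node(*left)
    root.right = Node(*right)
    t = StratificationTree(root=root, feature_names=[feature_name])
    t.assign_ids()
    return t


class TestEncoding:
    def test_indicator_counts_per_level_structure(self, default_cohort):
        cohort, _ = default_cohort
        X, names = encode_confounders(cohort, ["diabetes"])
        assert names == ["diabetes=yes"]
        X, names = encode_confounders(cohort, ["bmi"])
        assert sorted(names) == ["bmi=<18.5", "bmi=>=24"]
        X, names = encode_confounders(cohort, ["n_comorbidities"])
        assert len(names) == 2

    def test_indicators_match_column_contents(self, default_cohort):
        cohort, _ = default_cohort
        X, names = encode_confounders(cohort, ["diabetes"])
        assert (X[:, 0] == (cohort.data["diabetes"] == "yes").to_numpy()).all()


class TestGrowTree:
    def test_planted_dominant_indicator_is_the_root_split(self, rng):
        n = 1000
        X = rng.random((n, 6)) < 0.35
        p = np.where(X[:, 3], 0.30, 0.05)
        y = (rng.random(n) < p).astype(int)
        tree = grow_tree(X, y, [f"f{i}" for i in range(6)])
        assert tree.feature_names[tree.root.feature] == "f3"
        assert tree.root.feature == exhaustive_best_split(X, y)

    def test_chosen_split_equals_exhaustive_oracle(self, rng):
        for trial in range(25):
            n = int(rng.integers(40, 200))
            X = rng.random((n, 8)) < rng.uniform(0.2, 0.6)
            y = (rng.random(n) < rng.uniform(0.1, 0.5)).astype(int)
            tree = grow_tree(X, y, [f"f{i}" for i in range(8)])
            oracle = exhaustive_best_split(X, y)
            got = None if tree.root.is_leaf else tree.root.feature
            assert got == oracle

    def test_pure_outcome_node_stays_a_leaf(self, rng):
        X = rng.random((50, 4)) < 0.5
        y = np.zeros(50, dtype=int)
        assert grow_tree(X, y, list("abcd")).root.is_leaf

    def test_below_min_split_stays_a_leaf(self, rng):
        X = rng.random((19, 4)) < 0.5
        y = (rng.random(19) < 0.5).astype(int)
        assert grow_tree(X, y, list("abcd")).root.is_leaf

    def test_children_counts_sum_to_parent(self, rng):
        X = rng.random((500, 5)) < 0.4
        p = np.where(X[:, 0], 0.4, 0.1)
        y = (rng.random(500) < p).astype(int)
        tree = grow_tree(X, y, list("abcde"))
        for node in tree.root.internal_nodes():
            assert node.left.n + node.right.n == node.n
            assert node.left.events + node.right.events == node.events


def _splits(tree):
    out = set()

    def visit(node, path):
        if node.is_leaf:
            return
        out.add((path, node.feature))
        visit(node.left, path + "L")
        visit(node.right, path + "R")

    visit(tree.root, "")
    return out


class TestCostComplexityPath:
    def test_single_leaf_path(self):
        path = cost_complexity_path(leaf_tree(30, 3))
        assert len(path) == 1 and path[0][0] == 0.0

    def test_two_leaf_path_ends_at_root(self):
        tree = manual_split_tree("f", (50, 2), (50, 20))
        path = cost_complexity_path(tree)
        assert len(path) == 2
        assert path[-1][1].root.is_leaf

    def test_path_is_nested_with_nondecreasing_alphas(self, rng):
        n = 600
        X = rng.random((n, 6)) < 0.4
        p = 0.05 + 0.25 * X[:, 0] + 0.15 * X[:, 1]
        y = (rng.random(n) < p).astype(int)
        full = grow_tree(X, y, [f"f{i}" for i in range(6)])
        path = cost_complexity_path(full)
        alphas = [a for a, _ in path]
        assert alphas == sorted(alphas)
        full_splits = _splits(full)
        prev_splits = full_splits
        for _, sub in path:
            s = _splits(sub)
            assert s <= full_splits, "pruned tree must be a subtree of the full tree"
            assert s <= prev_splits, "path subtrees must be nested"
            prev_splits = s
        assert path[-1][1].root.is_leaf


class TestCvPrune:
    def test_pure_noise_selects_the_root_only_tree(self):
        root_only = 0
        for s in range(10):
            rng = np.random.default_rng(s)
            X = rng.random((800, 6)) < 0.4
            y = (rng.random(800) < 0.1).astype(int)
            t = cv_prune(X, y, [f"f{i}" for i in range(6)], folds=5, seed=s)
            root_only += t.root.is_leaf
        assert root_only >= 7

    def test_dominant_planted_split_is_retained(self):
        kept = 0
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            X = rng.random((2000, 6)) < 0.3
            p = np.where(X[:, 2], 0.30, 0.05)
            y = (rng.random(2000) < p).astype(int)
            t = cv_prune(X, y, [f"f{i}" for i in range(6)], folds=5, seed=s)
            kept += "f2" in {t.feature_names[n.feature] for n in t.root.internal_nodes()}
        assert kept >= 9

    def test_two_folds_on_forty_subjects_partitions_everyone(self, rng):
        X = rng.random((40, 3)) < 0.5
        y = np.array([1] * 8 + [0] * 32)
        t = cv_prune(X, y, list("abc"), folds=2, seed=1)
        leaf = t.apply(X)
        assert len(leaf) == 40
        assert sum(l.n for l in t.root.leaves()) == 40

    def test_same_seed_is_bit_reproducible(self, rng):
        X = rng.random((500, 5)) < 0.4
        p = np.where(X[:, 1], 0.3, 0.08)
        y = (rng.random(500) < p).astype(int)
        t1 = cv_prune(X, y, list("abcde"), folds=5, seed=9)
        t2 = cv_prune(X, y, list("abcde"), folds=5, seed=9)
        assert t1.to_json() == t2.to_json()

    def test_fold_without_both_classes_is_refused(self, rng):
        X = rng.random((60, 3)) < 0.5
        y = np.array([1] * 3 + [0] * 57)  # 3 events cannot stratify 10 folds
        with pytest.raises(EstimationError, match="fewer folds"):
            cv_prune(X, y, list("abc"), folds=10, seed=1)


class TestTreeAic:
    def test_root_only_closed_form(self):
        n, e = 200, 30
        p = e / n
        expected = n * (-2) * (p * math.log(p) + (1 - p) * math.log(1 - p)) + 2
        assert tree_aic(leaf_tree(n, e)) == pytest.approx(expected)

    def test_uninformative_split_costs_exactly_two(self):
        split = manual_split_tree("f", (50, 5), (50, 5))
        merged = leaf_tree(100, 10)
        assert tree_aic(split) - tree_aic(merged) == pytest.approx(2.0)

    def test_informative_split_lowers_aic(self, rng):
        n = 2000
        X = rng.random((n, 1)) < 0.3
        p = np.where(X[:, 0], 0.35, 0.05)
        y = (rng.random(n) < p).astype(int)
        split = grow_tree(X, y, ["f"], min_split=20)
        assert not split.root.is_leaf
        assert tree_aic(split) < tree_aic(leaf_tree(n, int(y.sum())))

    def test_pure_leaf_uses_the_epsilon_clamp(self):
        t = manual_split_tree("f", (50, 0), (50, 25))
        assert math.isfinite(tree_aic(t))


class TestModelSelection:
    def test_printed_aics_select_the_full_confounder_model(self):
        cands = [
            CandidateModel("model1", ["a"], leaf_tree(10, 1), 3056.8),
            CandidateModel("model2", ["a", "b"], leaf_tree(10, 1), 2943.7),
            CandidateModel("model3", ["a", "b", "c"], leaf_tree(10, 1), 2907.4),
        ]
        assert select_model(cands).model_id == "model3"

    def test_single_candidate_returns_itself(self):
        c = CandidateModel("m", ["a"], leaf_tree(10, 1), 5.0)
        assert select_model([c]) is c

    def test_tie_prefers_the_smaller_confounder_set(self):
        cands = [
            CandidateModel("big", ["a", "b"], leaf_tree(10, 1), 7.0),
            CandidateModel("small", ["a"], leaf_tree(10, 1), 7.0),
        ]
        assert select_model(cands).model_id == "small"


class TestStrata:
    def test_root_only_tree_puts_everyone_in_one_stratum(self, default_cohort):
        cohort, _ = default_cohort
        t = leaf_tree(cohort.n_subjects, int(cohort.outcome.sum()))
        t.confounders = ["diabetes"]
        t.feature_names = ["diabetes=yes"]
        labels = assign_strata(t, cohort)
        assert len(set(labels)) == 1

    def test_leaves_partition_and_siblings_are_disjoint(self, rng, default_cohort):
        cohort, _ = default_cohort
        X, names = encode_confounders(cohort, ["age", "diabetes", "malignant_tumor"])
        tree = grow_tree(X, cohort.outcome, names)
        tree.confounders = ["age", "diabetes", "malignant_tumor"]
        labels = assign_strata(tree, cohort)
        leaves = tree.root.leaves()
        assert len(set(labels)) == len(leaves)
        counts = {l.node_id: l.n for l in leaves}
        for leaf_id, n in counts.items():
            assert (labels == leaf_id).sum() == n


class TestPairwiseNodeEffects:
    def test_published_root_split_risk_ratio(self):
        tree = manual_split_tree("cerebrovascular_disease=yes", (7190, 363), (112, 34))
        est = pairwise_node_effects(tree)[0]
        assert round(est.point, 2) == 6.01
        assert est.measure == "risk-ratio"

    def test_identical_child_incidences_give_unity(self):
        tree = manual_split_tree("f", (100, 10), (50, 5))
        assert pairwise_node_effects(tree)[0].point == pytest.approx(1.0)

    def test_toy_division(self):
        tree = manual_split_tree("f", (10, 1), (10, 2))
        assert pairwise_node_effects(tree)[0].point == pytest.approx(2.0)
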