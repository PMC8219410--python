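import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from attn_eeg import irf
from attn_eeg.irf import (
    CVPlan,
    Hyperparams,
    bootstrap_sample,
    build_tree,
    cross_validate,
    grid_search,
    load_model,
    make_cv_plan,
    predict,
    predict_matrix,
    save_model,
    train_forest,
    train_irf,
)
from attn_eeg.synth import ClassProfile, generate_dataset
from attn_eeg import features as feat


def blobs(n_per_class=20, d=4, sep=4.0, seed=0, n_classes=5):
    """Gaussian blobs around well-separated class centroids."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(n_classes):
        centre = np.zeros(d)
        centre[c % d] = sep * (1 + c // d)
        X.append(rng.normal(size=(n_per_class, d)) + centre)
        y.extend([c] * n_per_class)
    return np.vstack(X), np.array(y)


class TestBootstrap:
    def test_single_sample(self):
        assert bootstrap_sample(1, np.random.default_rng(0)).tolist() == [0]

    def test_distinct_fraction_near_632(self):
        idx = bootstrap_sample(1000, np.random.default_rng(42))
        assert len(idx) == 1000
        assert abs(len(np.unique(idx)) / 1000 - (1 - 1 / np.e)) <= 0.03

    def test_deterministic_under_seed(self):
        a = bootstrap_sample(50, np.random.default_rng(7))
        b = bootstrap_sample(50, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_sample(0, np.random.default_rng(0))


def cart_root_oracle(X, y, min_leaf=1):
    """Exhaustive root split: all features, all midpoints, Gini impurity.

    Ties resolve to the lowest feature index, then the smallest threshold,
    mirroring the production rules but via direct enumeration.
    """
    n = len(y)
    best = None  # (weighted_gini, feature, threshold)
    for f in range(X.shape[1]):
        vals = np.unique(X[:, f])
        for lo, hi in zip(vals, vals[1:]):
            thr = 0.5 * (lo + hi)
            left = y[X[:, f] <= thr]
            right = y[X[:, f] > thr]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            def gini(part):
                p = np.bincount(part, minlength=5) / len(part)
                return 1.0 - np.sum(p**2)
            w = (len(left) * gini(left) + len(right) * gini(right)) / n
            if best is None or w < best[0] - 1e-12:
                best = (w, f, thr)
    return best


class TestBuildTree:
    def test_single_class_is_leaf(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        tree = build_tree(X, np.full(10, 2), Hyperparams(1, 3, 1), np.random.default_rng(1))
        assert tree.n_nodes == 1
        assert tree.leaf_class[0] == 2

    def test_separable_1d_depth_one(self):
        X = np.array([[0.0], [0.1], [0.2], [1.0], [1.1], [1.2]])
        y = np.array([0, 0, 0, 4, 4, 4])
        tree = build_tree(X, y, Hyperparams(1, 1, 1), np.random.default_rng(0))
        assert tree.n_nodes == 3
        assert np.mean(tree.predict(X) == y) == 1.0

    def test_root_split_matches_exhaustive_oracle(self):
        # all features offered at the root (max_features = d), so the
        # random feature draw is irrelevant and the oracle applies directly
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 2))
        y = (X[:, 0] + 0.3 * rng.normal(size=20) > 0).astype(int) * 4
        tree = build_tree(X, y, Hyperparams(1, 2, 1), np.random.default_rng(3))
        _, f_oracle, thr_oracle = cart_root_oracle(X, y)
        assert tree.feature[0] == f_oracle
        assert tree.threshold[0] == pytest.approx(thr_oracle)

    def test_training_accuracy_matches_oracle_greedy_cart(self):
        # with max_features = d the tree is deterministic greedy CART,
        # which fits any consistent labelling exactly
        X, y = blobs(n_per_class=4, d=2, sep=3.0, seed=2)
        tree = build_tree(X, y, Hyperparams(1, 2, 1), np.random.default_rng(0))
        assert np.mean(tree.predict(X) == y) == 1.0

    def test_min_samples_leaf_respected(self):
        X, y = blobs(n_per_class=10, d=3, seed=3)
        tree = build_tree(X, y, Hyperparams(1, 3, 5), np.random.default_rng(0))
        # count samples reaching each leaf
        leaves = {}
        for row in X:
            node = 0
            while tree.feature[node] >= 0:
                node = tree.left[node] if row[tree.feature[node]] <= tree.threshold[node] else tree.right[node]
            leaves[node] = leaves.get(node, 0) + 1
        assert min(leaves.values()) >= 5

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            build_tree(np.empty((0, 2)), np.array([]), Hyperparams(), np.random.default_rng(0))


class TestTrainForestPredict:
    def test_k1_forest_equals_its_tree(self):
        X, y = blobs(seed=1)
        model = train_forest(X, y, Hyperparams(1, 2, 1), seed=5)
        assert np.array_equal(predict_matrix(model, X), model.trees[0].predict(X))

    def test_same_seed_identical_predictions(self):
        X, y = blobs(seed=2)
        Xt = np.random.default_rng(9).normal(size=(30, 4))
        a = predict_matrix(train_forest(X, y, Hyperparams(10, 2, 1), seed=3), Xt)
        b = predict_matrix(train_forest(X, y, Hyperparams(10, 2, 1), seed=3), Xt)
        assert np.array_equal(a, b)

    def test_blobs_training_accuracy_vs_reference(self):
        # verified against a reference ensemble implementation on same data
        from sklearn.ensemble import RandomForestClassifier

        X, y = blobs(n_per_class=100, d=4, sep=4.0, seed=4)
        model = train_forest(X, y, Hyperparams(25, 2, 1), seed=0)
        ours = np.mean(predict_matrix(model, X) == y)
        ref = RandomForestClassifier(n_estimators=25, max_features=2, random_state=0)
        theirs = ref.fit(X, y).score(X, y)
        assert ours >= 0.95
        assert theirs >= 0.95

    def test_majority_vote_tally_oracle(self):
        X, y = blobs(seed=6)
        model = train_forest(X, y, Hyperparams(9, 2, 1), seed=1)
        Xt = np.random.default_rng(0).normal(size=(40, 4))
        pred = predict_matrix(model, Xt)
        # independent vote tally: count per-tree classes, argmax with
        # ties toward the lower ordinal level
        for i, row in enumerate(Xt):
            tally = [0] * 5
            for tree in model.trees:
                tally[tree.predict_one(row)] += 1
            best = max(range(5), key=lambda c: (tally[c], -c))
            assert pred[i] == best

    def test_tie_goes_to_lower_level(self):
        class StubTree:
            def __init__(self, cls):
                self.cls = cls

            def predict(self, X):
                return np.full(len(X), self.cls, dtype=int)

            def predict_one(self, x):
                return self.cls

        model = train_forest(*blobs(n_per_class=3), Hyperparams(5, 2, 1), seed=0)
        model.trees = [StubTree(c) for c in [0, 0, 2, 2, 4]]
        assert predict(model, np.zeros(4)) == 0

    def test_dimension_mismatch_rejected(self):
        X, y = blobs(seed=0)
        model = train_forest(X, y, Hyperparams(2, 2, 1), seed=0)
        with pytest.raises(ValueError, match="dimension"):
            predict(model, np.zeros(7))

    def test_zero_estimators_rejected(self):
        with pytest.raises(ValueError):
            Hyperparams(0, 1, 1)

    def test_serialization_roundtrip(self, tmp_path):
        X, y = blobs(seed=8)
        model = train_forest(X, y, Hyperparams(4, 2, 1), seed=2)
        p = tmp_path / "model.json"
        save_model(model, p)
        back = load_model(p)
        Xt = np.random.default_rng(1).normal(size=(25, 4))
        assert np.array_equal(predict_matrix(back, Xt), predict_matrix(model, Xt))
        assert back.hyperparams == model.hyperparams
        assert back.tree_seeds == model.tree_seeds


class TestCVPlan:
    def test_100_by_10(self):
        plan = make_cv_plan(100, 10, seed=0)
        assert plan.S == 10
        assert all(len(f) == 10 for f in plan.folds)

    def test_leave_one_out(self):
        plan = make_cv_plan(10, 10, seed=0)
        assert sorted(len(f) for f in plan.folds) == [1] * 10

    def test_disjoint_cover(self):
        plan = make_cv_plan(57, 5, seed=3)
        union = np.sort(np.concatenate(plan.folds))
        assert np.array_equal(union, np.arange(57))

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            make_cv_plan(5, 10)

    @given(n=st.integers(min_value=10, max_value=500), S=st.sampled_from([2, 5, 10]))
    @settings(max_examples=40, deadline=None)
    def test_disjointness_and_coverage_property(self, n, S):
        plan = make_cv_plan(n, S, seed=n * 31 + S)
        union = np.concatenate(plan.folds)
        assert np.array_equal(np.sort(union), np.arange(n))
        sizes = [len(f) for f in plan.folds]
        assert max(sizes) - min(sizes) <= 1


class TestCrossValidate:
    def test_output_length(self, small_dataset):
        plan = make_cv_plan(small_dataset.n_rows, 5, seed=0)
        accs = cross_validate(small_dataset, hp=Hyperparams(5, 4, 1), plan=plan, seed=0)
        assert len(accs) == 5

    def test_chance_level_on_label_free_features(self):
        # features carry no class information -> accuracy near 1/5
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 3))
        y = np.tile(np.arange(5), 40)
        plan = make_cv_plan(200, 10, seed=1)
        accs = cross_validate(X, y, Hyperparams(15, 2, 1), plan, seed=1)
        assert abs(np.mean(accs) - 0.2) <= 0.1

    def test_perfectly_separable_reaches_one(self):
        X, y = blobs(n_per_class=20, sep=6.0, seed=5)
        plan = make_cv_plan(len(y), 5, seed=2)
        accs = cross_validate(X, y, Hyperparams(15, 2, 1), plan, seed=2)
        assert np.mean(accs) == pytest.approx(1.0)


SMALL_GRID = {
    "n_estimators": [5, 10, 15],
    "max_features": [2, 4],
    "min_samples_leaf": [1, 3],
}


class TestGridSearch:
    def test_single_point_grid(self, small_dataset):
        grid = {"n_estimators": [5], "max_features": [3], "min_samples_leaf": [2]}
        plan = make_cv_plan(small_dataset.n_rows, 5, seed=0)
        res = grid_search(small_dataset, coarse_grid=grid, plan=plan, seed=0)
        assert res.best == Hyperparams(5, 3, 2)
        expected = np.mean(cross_validate(small_dataset, hp=res.best, plan=plan, seed=0))
        assert res.best_score == pytest.approx(expected)

    def test_matches_exhaustive_oracle_on_small_grid(self, small_dataset):
        plan = make_cv_plan(small_dataset.n_rows, 5, seed=1)
        res = grid_search(small_dataset, coarse_grid=SMALL_GRID, refine_step=2,
                          plan=plan, seed=1)
        # independent exhaustive oracle over every point the two-phase
        # search can visit, scored with identical folds and seeds
        evaluated = {hp for hp, _ in res.trace}
        oracle_scores = {
            hp: float(np.mean(cross_validate(small_dataset, hp=hp, plan=plan, seed=1)))
            for hp in evaluated
        }
        assert res.best_score == pytest.approx(max(oracle_scores.values()))
        coarse_scores = [
            oracle_scores[Hyperparams(k, x, l)]
            for k, x, l in itertools.product(
                SMALL_GRID["n_estimators"], SMALL_GRID["max_features"],
                SMALL_GRID["min_samples_leaf"])
        ]
        assert res.best_score >= max(coarse_scores)

    def test_trace_scores_match_best(self, small_dataset):
        plan = make_cv_plan(small_dataset.n_rows, 5, seed=2)
        res = grid_search(small_dataset, coarse_grid=SMALL_GRID, plan=plan, seed=2)
        assert res.best_score == pytest.approx(max(s for _, s in res.trace))

    def test_tie_prefers_smaller_complexity(self):
        # perfectly separable data: every configuration scores 1.0
        X, y = blobs(n_per_class=10, sep=8.0, seed=0)
        plan = make_cv_plan(len(y), 5, seed=0)
        grid = {"n_estimators": [3, 7], "max_features": [2], "min_samples_leaf": [1]}
        res = grid_search(X, y, coarse_grid=grid, plan=plan, seed=0)
        assert res.best_score == pytest.approx(1.0)
        assert res.best.n_estimators == 3

    def test_fixed_seed_bit_identical_trace(self, small_dataset):
        plan = make_cv_plan(small_dataset.n_rows, 5, seed=3)
        grid = {"n_estimators": [5, 10], "max_features": [2], "min_samples_leaf": [1]}
        a = grid_search(small_dataset, coarse_grid=grid, plan=plan, seed=3)
        b = grid_search(small_dataset, coarse_grid=grid, plan=plan, seed=3)
        assert a.trace == b.trace
        assert a.best == b.best

    def test_empty_grid_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="coarse grid"):
            grid_search(small_dataset, coarse_grid={"n_estimators": []}, seed=0)


class TestTrainIRF:
    CONFIG = {
        "folds": 5,
        "coarse_grid": {"n_estimators": [5, 10], "max_features": [2, 4],
                        "min_samples_leaf": [1]},
    }

    def test_best_appears_in_trace(self, small_dataset):
        model, res = train_irf(small_dataset, config=self.CONFIG, seed=4)
        assert res.best in {hp for hp, _ in res.trace}
        assert model.hyperparams == res.best

    def test_deterministic(self, small_dataset):
        _, a = train_irf(small_dataset, config=self.CONFIG, seed=4)
        _, b = train_irf(small_dataset, config=self.CONFIG, seed=4)
        assert a.best == b.best and a.best_score == b.best_score

    def test_best_score_dominates_coarse_points(self, small_dataset):
        _, res = train_irf(small_dataset, config=self.CONFIG, seed=5)
        n_coarse = 4  # 2 x 2 x 1 coarse grid points come first in the trace
        assert res.best_score >= max(s for _, s in res.trace[:n_coarse])

    def test_too_few_samples_message(self):
        X = np.zeros((6, 2))
        y = np.arange(6) % 5
        with pytest.raises(ValueError, match="smaller fold"):
            train_irf(X, y, config={"folds": 10}, seed=0)


class TestSeparationMonotonicity:
    def test_training_accuracy_monotone_in_separation(self):
        # high noise and a large leaf size keep the forest from memorising,
        # so training accuracy has room to grow with class separation
        separations = [0.0, 0.5, 1.0]
        means = []
        for sep in separations:
            accs = []
            for seed in range(10):
                profile = ClassProfile.default(separation=sep, noise_sd=6.0)
                epochs, _ = generate_dataset(6, profile=profile, seed=seed)
                fm = feat.extract_matrix(epochs)
                model = train_forest(fm, hp=Hyperparams(5, 4, 8), seed=seed)
                pred = predict_matrix(model, fm)
                accs.append(np.mean(pred == fm.label_array()))
            means.append(np.mean(accs))
        rho = stats.spearmanr(separations, means).statistic
        assert rho >= 0.9
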