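"""Improved random forest: bootstrap CART ensemble with majority voting,
coarse-to-fine grid-search hyperparameter optimisation and S-fold
cross-validation.

Trees are grown without pruning; at every node a random subset of
``max_features`` feature variables is drawn and the (feature, threshold)
pair minimising the Gini impurity of the children is chosen.  Ensemble
prediction is simple majority voting with ties broken toward the lower
ordinal attention level.  All randomness flows from one master seed through
named substreams, so every result is bit-reproducible.
"""

from __future__ import annotations

import itertools
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Hyperparams",
    "Tree",
    "ForestModel",
    "CVPlan",
    "GridSearchResult",
    "bootstrap_sample",
    "build_tree",
    "train_forest",
    "predict",
    "predict_matrix",
    "make_cv_plan",
    "cross_validate",
    "grid_search",
    "train_irf",
    "save_model",
    "load_model",
    "DEFAULT_COARSE_GRID",
]

N_CLASSES = 5

#: coarse phase-1 grid used when the caller supplies none
DEFAULT_COARSE_GRID = {
    "n_estimators": [50, 100, 150, 200, 250, 300],
    "max_features": [2, 4, 6, 8, 10, 12, 14, 16, 18, 20],
    "min_samples_leaf": [1, 3, 5, 9],
}


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Deterministic named RNG substream derived from one master seed."""
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag, int(index)]))


@dataclass(frozen=True, order=True)
class Hyperparams:
    """Forest hyperparameters; ordering doubles as the complexity tie-break key."""

    n_estimators: int = 100
    max_features: int = 4
    min_samples_leaf: int = 1

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.max_features < 1:
            raise ValueError("max_features must be >= 1")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")


@dataclass
class Tree:
    """CART tree as parallel arrays; feature == -1 marks a leaf."""

    feature: list[int]
    threshold: list[float]
    left: list[int]
    right: list[int]
    leaf_class: list[int]

    def predict_one(self, x: np.ndarray) -> int:
        node = 0
        while self.feature[node] >= 0:
            if x[self.feature[node]] <= self.threshold[node]:
                node = self.left[node]
            else:
                node = self.right[node]
        return self.leaf_class[node]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.array([self.predict_one(row) for row in X], dtype=int)

    @property
    def n_nodes(self) -> int:
        return len(self.feature)


@dataclass
class ForestModel:
    trees: list[Tree]
    tree_seeds: list[int]
    classes: list[int]
    hyperparams: Hyperparams
    n_features: int

    def __post_init__(self) -> None:
        if len(self.trees) != self.hyperparams.n_estimators:
            raise ValueError("tree count does not match n_estimators")


@dataclass
class CVPlan:
    """S pairwise-disjoint index folds covering 0..n-1, sizes differing <= 1."""

    folds: list[np.ndarray]

    def __post_init__(self) -> None:
        all_idx = np.concatenate(self.folds) if self.folds else np.array([], dtype=int)
        n = all_idx.size
        if n == 0:
            raise ValueError("empty cross-validation plan")
        if np.unique(all_idx).size != n or all_idx.min() != 0 or all_idx.max() != n - 1:
            raise ValueError("folds must be disjoint and cover 0..n-1")
        sizes = [len(f) for f in self.folds]
        if min(sizes) == 0:
            raise ValueError("empty fold in cross-validation plan")
        if max(sizes) - min(sizes) > 1:
            raise ValueError("fold sizes must differ by at most one")

    @property
    def S(self) -> int:
        return len(self.folds)

    @property
    def n(self) -> int:
        return sum(len(f) for f in self.folds)


@dataclass
class GridSearchResult:
    best: Hyperparams
    best_score: float
    trace: list[tuple[Hyperparams, float]] = field(default_factory=list)


def _as_xy(features, labels=None):
    """Accept a FeatureMatrix or a plain array (+ labels)."""
    if hasattr(features, "values") and hasattr(features, "feature_names"):
        X = np.asarray(features.values, dtype=float)
        if labels is None and features.labels is not None:
            labels = features.label_array()
    else:
        X = np.asarray(features, dtype=float)
    if labels is None:
        raise ValueError("labels are required")
    y = np.array([int(v) for v in np.asarray(labels).ravel()])
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features and labels misaligned")
    if X.shape[0] == 0:
        raise ValueError("empty training data")
    if y.min() < 0 or y.max() >= N_CLASSES:
        raise ValueError(f"labels must lie in 0..{N_CLASSES - 1}")
    return X, y


def bootstrap_sample(n: int, rng: np.random.Generator) -> np.ndarray:
    """n indices drawn uniformly with replacement (one bootstrap resample)."""
    if n < 1:
        raise ValueError("cannot bootstrap an empty dataset")
    return rng.integers(0, n, size=n)


def _best_split(X, y, idx, feat_candidates, min_leaf):
    """Exhaustive threshold scan over the drawn features.

    Returns (feature, threshold, left_idx, right_idx) or None.  Ties in
    impurity go to the lowest feature index, then the smallest threshold
    (candidates are scanned in that order and only strict improvements
    replace the incumbent).
    """
    n = idx.size
    best = None
    best_score = -np.inf  # maximise sum of squared class proportions
    y_node = y[idx]
    for f in feat_candidates:
        v = X[idx, f]
        order = np.argsort(v, kind="stable")
        vs = v[order]
        ys = y_node[order]
        onehot = np.zeros((n, N_CLASSES))
        onehot[np.arange(n), ys] = 1.0
        cum = np.cumsum(onehot, axis=0)
        n_left = np.arange(1, n + 1, dtype=float)
        total = cum[-1]
        sq_left = (cum**2).sum(axis=1) / n_left
        right = total[None, :] - cum
        n_right = n - n_left
        with np.errstate(divide="ignore", invalid="ignore"):
            sq_right = (right**2).sum(axis=1) / n_right
        score = sq_left + np.where(n_right > 0, sq_right, 0.0)
        pos = np.flatnonzero(
            (vs[:-1] < vs[1:])
            & (n_left[:-1] >= min_leaf)
            & (n_right[:-1] >= min_leaf)
        )
        if pos.size == 0:
            continue
        local = pos[np.argmax(score[pos])]  # first max = smallest threshold
        if score[local] > best_score + 1e-12:
            best_score = score[local]
            thr = 0.5 * (vs[local] + vs[local + 1])
            mask = v <= thr
            best = (int(f), float(thr), idx[mask], idx[~mask])
    return best


def build_tree(features, labels, hp: Hyperparams, rng: np.random.Generator) -> Tree:
    """Grow an unpruned CART tree with per-node random feature subsets."""
    X, y = _as_xy(features, labels)
    d = X.shape[1]
    x_try = min(hp.max_features, d)
    tree = Tree(feature=[], threshold=[], left=[], right=[], leaf_class=[])

    def new_node() -> int:
        tree.feature.append(-1)
        tree.threshold.append(0.0)
        tree.left.append(-1)
        tree.right.append(-1)
        tree.leaf_class.append(-1)
        return len(tree.feature) - 1

    root = new_node()
    stack = [(root, np.arange(X.shape[0]))]
    while stack:
        node, idx = stack.pop()
        counts = np.bincount(y[idx], minlength=N_CLASSES)
        majority = int(np.argmax(counts))  # tie -> lower ordinal class
        pure = counts.max() == idx.size
        if pure or idx.size < 2 * hp.min_samples_leaf:
            tree.leaf_class[node] = majority
            continue
        cand = np.sort(rng.choice(d, size=x_try, replace=False))
        split = _best_split(X, y, idx, cand, hp.min_samples_leaf)
        if split is None:
            tree.leaf_class[node] = majority
            continue
        f, thr, left_idx, right_idx = split
        tree.feature[node] = f
        tree.threshold[node] = thr
        lnode, rnode = new_node(), new_node()
        tree.left[node] = lnode
        tree.right[node] = rnode
        stack.append((rnode, right_idx))
        stack.append((lnode, left_idx))
    return tree


def train_forest(features, labels=None, hp: Hyperparams | None = None, seed: int = 0) -> ForestModel:
    """Fit ``hp.n_estimators`` trees, each on its own bootstrap resample."""
    hp = hp or Hyperparams()
    X, y = _as_xy(features, labels)
    master = substream(seed, "forest")
    tree_seeds = [int(s) for s in master.integers(0, 2**63 - 1, size=hp.n_estimators)]
    trees = []
    for ts in tree_seeds:
        rng = np.random.default_rng(ts)
        idx = bootstrap_sample(X.shape[0], rng)
        trees.append(build_tree(X[idx], y[idx], hp, rng))
    return ForestModel(
        trees=trees,
        tree_seeds=tree_seeds,
        classes=list(range(N_CLASSES)),
        hyperparams=hp,
        n_features=X.shape[1],
    )


def _tree_votes(model: ForestModel, X: np.ndarray) -> np.ndarray:
    """(n_samples, n_classes) vote tallies across the ensemble."""
    votes = np.zeros((X.shape[0], N_CLASSES), dtype=int)
    for tree in model.trees:
        pred = tree.predict(X)
        votes[np.arange(X.shape[0]), pred] += 1
    return votes


def predict_matrix(model: ForestModel, features) -> np.ndarray:
    X = features.values if hasattr(features, "values") else np.asarray(features, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model ({model.n_features})"
        )
    votes = _tree_votes(model, X)
    return votes.argmax(axis=1)  # argmax takes the first max: tie -> lower level


def predict(model: ForestModel, v) -> int:
    """Majority-vote class of a single feature vector."""
    vec = v.values if hasattr(v, "values") else np.asarray(v, dtype=float)
    vec = np.asarray(vec, dtype=float).ravel()
    return int(predict_matrix(model, vec[None, :])[0])


def make_cv_plan(n: int, S: int = 10, seed: int = 0) -> CVPlan:
    """Random permutation split into S near-equal disjoint folds."""
    if S < 2:
        raise ValueError("need at least 2 folds")
    if S > n:
        raise ValueError(f"cannot split {n} samples into {S} folds")
    perm = substream(seed, "cv-shuffle").permutation(n)
    return CVPlan(folds=[np.sort(f) for f in np.array_split(perm, S)])


def cross_validate(features, labels=None, hp: Hyperparams | None = None,
                   plan: CVPlan | None = None, seed: int = 0) -> list[float]:
    """Accuracy on each held-out fold (train on the S-1 others)."""
    hp = hp or Hyperparams()
    X, y = _as_xy(features, labels)
    if plan is None:
        plan = make_cv_plan(X.shape[0], 10, seed)
    if plan.n != X.shape[0]:
        raise ValueError("cross-validation plan does not match the data size")
    accs = []
    for i, test_idx in enumerate(plan.folds):
        train_mask = np.ones(X.shape[0], dtype=bool)
        train_mask[test_idx] = False
        fold_seed = int(substream(seed, "cv-fold", i).integers(0, 2**63 - 1))
        model = train_forest(X[train_mask], y[train_mask], hp, seed=fold_seed)
        pred = predict_matrix(model, X[test_idx])
        accs.append(float(np.mean(pred == y[test_idx])))
    return accs


def _refine_axis(coarse: Sequence[int], best_value: int, step: int,
                 lo_bound: int = 1, hi_bound: int | None = None) -> list[int]:
    """Fine grid spanning one coarse step either side of the winner."""
    axis = sorted(set(int(v) for v in coarse))
    i = axis.index(best_value)
    lo = axis[i - 1] if i > 0 else best_value
    hi = axis[i + 1] if i + 1 < len(axis) else best_value
    values = set(range(lo, hi + 1, step)) | {best_value}
    values = {v for v in values if v >= lo_bound}
    if hi_bound is not None:
        values = {v for v in values if v <= hi_bound}
    return sorted(values)


def grid_search(features, labels=None, coarse_grid: dict | None = None,
                refine_step: int = 2, plan: CVPlan | None = None,
                seed: int = 0) -> GridSearchResult:
    """Two-phase coarse-to-fine search over mean CV accuracy.

    Phase 1 scores every coarse grid point; phase 2 re-grids the
    neighbourhood (one coarse step either side of the winner, per axis) with
    ``refine_step`` and scores those points.  Ties resolve toward the
    smallest (n_estimators, max_features, min_samples_leaf).
    """
    X, y = _as_xy(features, labels)
    if refine_step < 1:
        raise ValueError("refine_step must be >= 1")
    grid = dict(DEFAULT_COARSE_GRID if coarse_grid is None else coarse_grid)
    for key in ("n_estimators", "max_features", "min_samples_leaf"):
        if not grid.get(key):
            raise ValueError(f"coarse grid is missing values for {key!r}")
    d = X.shape[1]
    grid["max_features"] = sorted({min(v, d) for v in grid["max_features"]})
    if plan is None:
        plan = make_cv_plan(X.shape[0], 10, seed)

    cache: dict[Hyperparams, float] = {}
    trace: list[tuple[Hyperparams, float]] = []

    def score(hp: Hyperparams) -> float:
        if hp not in cache:
            cache[hp] = float(np.mean(cross_validate(X, y, hp, plan, seed)))
        trace.append((hp, cache[hp]))
        return cache[hp]

    def sweep(axes: dict) -> Hyperparams:
        best_hp, best_key = None, None
        for k, x, leaf in itertools.product(
            axes["n_estimators"], axes["max_features"], axes["min_samples_leaf"]
        ):
            hp = Hyperparams(k, x, leaf)
            s = score(hp)
            key = (-s, hp)  # higher score first, then smaller complexity
            if best_key is None or key < best_key:
                best_hp, best_key = hp, key
        return best_hp

    coarse_best = sweep(grid)
    fine_axes = {
        "n_estimators": _refine_axis(grid["n_estimators"], coarse_best.n_estimators, refine_step),
        "max_features": _refine_axis(grid["max_features"], coarse_best.max_features, refine_step, hi_bound=d),
        "min_samples_leaf": _refine_axis(grid["min_samples_leaf"], coarse_best.min_samples_leaf, refine_step),
    }
    sweep(fine_axes)

    best = min(cache, key=lambda hp: (-cache[hp], hp))
    return GridSearchResult(best=best, best_score=cache[best], trace=trace)


def train_irf(features, labels=None, config: dict | None = None, seed: int = 0):
    """Grid search with S-fold CV, then a final fit on all training data.

    ``config`` keys: ``folds`` (default 10), ``coarse_grid``, ``refine_step``
    (default 2).  Returns ``(ForestModel, GridSearchResult)``.
    """
    X, y = _as_xy(features, labels)
    config = config or {}
    S = int(config.get("folds", 10))
    if X.shape[0] < S:
        raise ValueError(
            f"only {X.shape[0]} samples for {S}-fold cross-validation; "
            f"use a smaller fold count"
        )
    plan = make_cv_plan(X.shape[0], S, seed)
    result = grid_search(
        X, y,
        coarse_grid=config.get("coarse_grid"),
        refine_step=int(config.get("refine_step", 2)),
        plan=plan,
        seed=seed,
    )
    model = train_forest(X, y, result.best, seed=int(substream(seed, "final-fit").integers(0, 2**63 - 1)))
    return model, result


# ---------------------------------------------------------------------------
# serialization

_FORMAT_VERSION = 1


def save_model(model: ForestModel, path: str | Path) -> None:
    doc = {
        "format_version": _FORMAT_VERSION,
        "classes": model.classes,
        "n_features": model.n_features,
        "hyperparams": {
            "n_estimators": model.hyperparams.n_estimators,
            "max_features": model.hyperparams.max_features,
            "min_samples_leaf": model.hyperparams.min_samples_leaf,
        },
        "tree_seeds": model.tree_seeds,
        "trees": [
            {
                "feature": t.feature,
                "threshold": t.threshold,
                "left": t.left,
                "right": t.right,
                "leaf_class": t.leaf_class,
            }
            for t in model.trees
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> ForestModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {doc.get('format_version')!r}")
    trees = [Tree(**t) for t in doc["trees"]]
    return ForestModel(
        trees=trees,
        tree_seeds=doc["tree_seeds"],
        classes=doc["classes"],
        hyperparams=Hyperparams(**doc["hyperparams"]),
        n_features=doc["n_features"],
    )
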