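"""Metrics, classifier comparison harness and the paired t-test.

Accuracy is trace/total of the confusion matrix; recall and precision are
macro-averaged (unweighted class means), with zero-denominator classes
contributing 0 and flagged in the report.  The comparison harness scores
every classifier on byte-identical folds; the baselines delegate to
scikit-learn, while ``irf`` is this package's own ensemble.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import irf as _irf

__all__ = [
    "MetricReport",
    "confusion_matrix",
    "metrics",
    "holdout_split",
    "compare_classifiers",
    "paired_ttest",
    "BASELINE_CLASSIFIERS",
]

logger = logging.getLogger(__name__)

N_CLASSES = 5


@dataclass
class MetricReport:
    accuracy: float
    macro_recall: float
    macro_precision: float
    confusion: np.ndarray
    per_class_recall: list[float]
    per_class_precision: list[float]
    undefined_recall_classes: list[int] = field(default_factory=list)
    undefined_precision_classes: list[int] = field(default_factory=list)

    # 1 - accuracy and log-loss are *not* the paper-style "loss" column of
    # typical comparison tables; they are provided as clearly-named extras.
    @property
    def error_rate(self) -> float:
        return 1.0 - self.accuracy


def confusion_matrix(true_labels, pred_labels, n_classes: int = N_CLASSES) -> np.ndarray:
    """entry (i, j) = number of samples of true class i predicted as j."""
    t = np.array([int(v) for v in true_labels])
    p = np.array([int(v) for v in pred_labels])
    if t.size != p.size:
        raise ValueError(f"length mismatch: {t.size} true vs {p.size} predicted")
    if t.size == 0:
        raise ValueError("cannot build a confusion matrix from zero samples")
    if t.min() < 0 or p.min() < 0 or t.max() >= n_classes or p.max() >= n_classes:
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (t, p), 1)
    return cm


def metrics(confusion: np.ndarray) -> MetricReport:
    """Accuracy plus macro recall/precision from a confusion matrix."""
    cm = np.asarray(confusion)
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    k = cm.shape[0]
    diag = np.diag(cm).astype(float)
    row = cm.sum(axis=1).astype(float)
    col = cm.sum(axis=0).astype(float)
    rec, prec, no_rec, no_prec = [], [], [], []
    for i in range(k):
        if row[i] == 0:
            rec.append(0.0)
            no_rec.append(i)
        else:
            rec.append(diag[i] / row[i])
        if col[i] == 0:
            prec.append(0.0)
            no_prec.append(i)
        else:
            prec.append(diag[i] / col[i])
    return MetricReport(
        accuracy=float(diag.sum() / total),
        macro_recall=float(np.mean(rec)),
        macro_precision=float(np.mean(prec)),
        confusion=cm,
        per_class_recall=rec,
        per_class_precision=prec,
        undefined_recall_classes=no_rec,
        undefined_precision_classes=no_prec,
    )


def holdout_split(n: int, test_fraction: float = 0.3, seed: int = 0):
    """Seeded random train/test index split (default 70/30)."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    perm = _irf.substream(seed, "holdout").permutation(n)
    n_test = int(round(n * test_fraction))
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def _sklearn_baseline(name: str, seed: int):
    from sklearn.ensemble import AdaBoostClassifier, ExtraTreesClassifier, RandomForestClassifier
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC

    if name == "svm":
        return SVC(kernel="rbf", random_state=seed)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    if name == "et":
        return ExtraTreesClassifier(n_estimators=100, random_state=seed)
    if name == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise KeyError(name)


BASELINE_CLASSIFIERS = ("svm", "knn", "adaboost", "et", "rf")


class _DummyMajority:
    def fit(self, X, y):
        counts = np.bincount(y, minlength=N_CLASSES)
        self.cls_ = int(np.argmax(counts))
        return self

    def predict(self, X):
        return np.full(len(X), self.cls_, dtype=int)


def _fold_hash(plan: _irf.CVPlan) -> str:
    h = hashlib.sha256()
    for f in plan.folds:
        h.update(np.asarray(f, dtype=np.int64).tobytes())
        h.update(b"|")
    return h.hexdigest()[:16]


def compare_classifiers(features, labels=None, classifier_specs=None,
                        plan: _irf.CVPlan | None = None, seed: int = 0,
                        irf_hyperparams: _irf.Hyperparams | None = None) -> pd.DataFrame:
    """Mean +/- sd cross-validated accuracy per classifier, identical folds.

    ``classifier_specs`` is a list drawn from
    {svm, knn, adaboost, et, rf, irf, dummy}; at least two are required.
    """
    X, y = _irf._as_xy(features, labels)
    specs = list(classifier_specs or (*BASELINE_CLASSIFIERS, "irf"))
    if len(specs) < 2:
        raise ValueError("need at least two classifiers to compare")
    if plan is None:
        plan = _irf.make_cv_plan(X.shape[0], 10, seed)
    logger.info("comparing %s on folds %s", specs, _fold_hash(plan))

    rows = []
    for spec in specs:
        if spec == "irf":
            accs = _irf.cross_validate(
                X, y, irf_hyperparams or _irf.Hyperparams(), plan, seed
            )
        elif spec == "dummy" or spec in BASELINE_CLASSIFIERS:
            accs = []
            for test_idx in plan.folds:
                mask = np.ones(X.shape[0], dtype=bool)
                mask[test_idx] = False
                clf = _DummyMajority() if spec == "dummy" else _sklearn_baseline(spec, seed)
                clf.fit(X[mask], y[mask])
                accs.append(float(np.mean(clf.predict(X[test_idx]) == y[test_idx])))
        else:
            raise KeyError(
                f"unknown classifier spec {spec!r}; expected one of "
                f"{(*BASELINE_CLASSIFIERS, 'irf', 'dummy')}"
            )
        rows.append({
            "classifier": spec,
            "mean_accuracy": float(np.mean(accs)),
            "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
            "accuracies": accs,
            "fold_hash": _fold_hash(plan),
        })
    return pd.DataFrame(rows)


def paired_ttest(acc_a, acc_b) -> tuple[float, float]:
    """Two-sided paired t-test on aligned accuracy lists.

    Zero-variance differences are handled as degenerate cases: identical
    vectors give (0, 1); a constant nonzero difference gives (+/-inf, 0).
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("need at least two paired observations")
    diff = a - b
    if np.all(diff == diff[0]):
        if diff[0] == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff[0]), 0.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
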