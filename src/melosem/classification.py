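"""Leave-k-pianists-out Gaussian Naive Bayes classification.

The pipeline mirrors a pianist-disjoint generalization test: features are
Z-scored with statistics fit on the training pianists only, a Gaussian NB
model is fit, and the held-out pianists' improvisations are scored with the
F1 metric (macro-averaged over both classes).  With 19 pianists and test
sets of 4, every fold trains on 480 improvisations and tests on 128 for the
cross-category tasks; all C(19,4) = 3876 folds are enumerable, and a seeded
subsample is available for quick runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES

log = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-9

#: task label -> (row filter column/value or None, label column)
TASKS = {
    "valence-all": (None, "valence"),
    "category-all": (None, "category"),
    "valence-morality": (("category", "morality"), "valence"),
    "valence-logic": (("category", "logic"), "valence"),
}


@dataclass(frozen=True)
class GnbModel:
    classes: tuple[str, ...]
    priors: np.ndarray          # (n_classes,)
    means: np.ndarray           # (n_classes, n_features)
    variances: np.ndarray       # (n_classes, n_features), floored

    def __post_init__(self) -> None:
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("class priors must sum to 1")
        if np.any(self.variances < VARIANCE_FLOOR):
            raise ValueError("variances below floor")


@dataclass
class FoldResult:
    test_pianists: tuple[str, ...]
    n_train: int
    n_test: int
    f1: float
    precision: float
    recall: float


@dataclass
class CvResult:
    task: str
    features: tuple[str, ...]
    folds: list[FoldResult] = field(default_factory=list)

    @property
    def fold_f1(self) -> np.ndarray:
        return np.array([f.f1 for f in self.folds])

    @property
    def mean_f1(self) -> float:
        return float(self.fold_f1.mean())

    @property
    def sd_f1(self) -> float:
        return float(self.fold_f1.std(ddof=1)) if len(self.folds) > 1 else 0.0


def zscore_fit_apply(
    train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize features with mean/sd estimated on the training rows only.

    Zero-variance training features map to 0 everywhere (with a warning):
    they carry no information at training scale.
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if train.shape[0] < 2:
        raise ValueError("need at least 2 training rows to estimate scale")
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    dead = sd == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} constant feature(s) mapped to 0", stacklevel=2)
        sd = np.where(dead, 1.0, sd)
    z_train = (train - mean) / sd
    z_test = (test - mean) / sd
    z_train[:, dead] = 0.0
    z_test[:, dead] = 0.0
    return z_train, z_test


def gnb_fit(features: np.ndarray, labels) -> GnbModel:
    """Fit class priors and per-feature Gaussian moments (variance floored)."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = tuple(np.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError("training set contains a single class")
    priors, means, variances = [], [], []
    for cls in classes:
        rows = features[labels == cls]
        priors.append(len(rows) / len(features))
        means.append(rows.mean(axis=0))
        variances.append(np.maximum(rows.var(axis=0), VARIANCE_FLOOR))
    return GnbModel(
        classes=classes,
        priors=np.array(priors),
        means=np.array(means),
        variances=np.array(variances),
    )


def gnb_log_posterior(model: GnbModel, features: np.ndarray) -> np.ndarray:
    """Unnormalized log posterior per class under independent Gaussians."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    ll = np.log(model.priors)[None, :] - 0.5 * np.sum(
        np.log(2 * np.pi * model.variances)[None, :, :]
        + (x[:, None, :] - model.means[None, :, :]) ** 2 / model.variances[None, :, :],
        axis=2,
    )
    return ll


def gnb_predict(model: GnbModel, features: np.ndarray):
    """Maximum-posterior labels and normalized posteriors.

    Ties break deterministically toward the class listed first in
    ``model.classes`` (sorted label order).
    """
    ll = gnb_log_posterior(model, features)
    idx = np.argmax(ll, axis=1)  # argmax returns the first maximum: tie-break
    shifted = ll - ll.max(axis=1, keepdims=True)
    post = np.exp(shifted)
    post /= post.sum(axis=1, keepdims=True)
    labels = np.array(model.classes, dtype=object)[idx]
    return labels, post


def binary_scores(predictions, labels, positive_class) -> tuple[float, float, float, float]:
    """(precision, recall, harmonic F1, geometric F1) for one positive class.

    Precision with no predicted positives is reported as 0 (flagged by a
    warning) rather than raising.
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels differ in length")
    tp = np.sum((predictions == positive_class) & (labels == positive_class))
    fp = np.sum((predictions == positive_class) & (labels != positive_class))
    fn = np.sum((predictions != positive_class) & (labels == positive_class))
    if tp + fp == 0:
        warnings.warn(f"no predicted positives for {positive_class!r}; precision set to 0", stacklevel=2)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    harmonic = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    geometric = float(np.sqrt(precision * recall))
    return float(precision), float(recall), float(harmonic), geometric


def f1_score(predictions, labels, mean: str = "harmonic") -> tuple[float, float, float]:
    """Macro-averaged (precision, recall, F1) over the two classes.

    ``mean`` selects the precision/recall combination: ``"harmonic"`` (the
    standard F1, default) or ``"geometric"``.
    """
    if mean not in ("harmonic", "geometric"):
        raise ValueError("mean must be 'harmonic' or 'geometric'")
    classes = np.unique(labels)
    ps, rs, fs = [], [], []
    for cls in classes:
        p, r, fh, fg = binary_scores(predictions, labels, cls)
        ps.append(p)
        rs.append(r)
        fs.append(fh if mean == "harmonic" else fg)
    return float(np.mean(ps)), float(np.mean(rs)), float(np.mean(fs))


def _task_rows(table: pd.DataFrame, task: str) -> tuple[pd.DataFrame, str]:
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; choose from {sorted(TASKS)}")
    row_filter, label_col = TASKS[task]
    rows = table if row_filter is None else table[table[row_filter[0]] == row_filter[1]]
    return rows.reset_index(drop=True), label_col


def pianist_folds(pianists, k: int, max_folds: int | None = None, seed: int | None = None):
    """Test-pianist subsets: all C(n, k) combinations, or a seeded uniform
    sample of ``max_folds`` of them (without replacement)."""
    pianists = list(pianists)
    if not 0 < k < len(pianists):
        raise ValueError("need 0 < k < number of pianists")
    n_total = comb(len(pianists), k)
    if max_folds is None or max_folds >= n_total:
        return [tuple(c) for c in combinations(pianists, k)]
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_total, size=max_folds, replace=False)
    all_combos = combinations(pianists, k)
    wanted = set(chosen.tolist())
    return [tuple(c) for i, c in enumerate(all_combos) if i in wanted]


def leave_k_pianists_out(
    table: pd.DataFrame,
    task: str,
    k: int = 4,
    features=tuple(FEATURE_NAMES),
    max_folds: int | None = None,
    seed: int | None = None,
    mean: str = "harmonic",
    labels=None,
) -> CvResult:
    """Pianist-disjoint cross-validation of a Gaussian NB classifier.

    ``features`` selects the columns used (a single name for per-dimension
    scores, the full 12 for the joint model).  ``labels`` optionally replaces
    the task's label column (e.g. a permuted copy for chance-level runs) and
    must align with the task's row subset.

    NaN feature values are imputed with the training-fold feature mean before
    Z-scoring.
    """
    if isinstance(features, str):
        features = (features,)
    features = tuple(features)
    rows, label_col = _task_rows(table, task)
    y_all = np.asarray(rows[label_col] if labels is None else labels)
    if len(y_all) != len(rows):
        raise ValueError("labels length does not match task rows")
    pianists = list(dict.fromkeys(rows["pianist_id"]))
    per_pianist = rows["pianist_id"].value_counts()
    if per_pianist.nunique() != 1:
        raise ValueError("pianists have unequal task row counts")
    x_all = rows[list(features)].to_numpy(dtype=float)
    pid = rows["pianist_id"].to_numpy()

    result = CvResult(task=task, features=features)
    for test_set in pianist_folds(pianists, k, max_folds, seed):
        test_mask = np.isin(pid, test_set)
        x_train, x_test = x_all[~test_mask], x_all[test_mask]
        y_train, y_test = y_all[~test_mask], y_all[test_mask]
        col_mean = np.nanmean(x_train, axis=0)
        x_train = np.where(np.isnan(x_train), col_mean, x_train)
        x_test = np.where(np.isnan(x_test), col_mean, x_test)
        z_train, z_test = zscore_fit_apply(x_train, x_test)
        model = gnb_fit(z_train, y_train)
        pred, _ = gnb_predict(model, z_test)
        precision, recall, f1 = f1_score(pred, y_test, mean=mean)
        result.folds.append(
            FoldResult(
                test_pianists=tuple(test_set),
                n_train=len(x_train),
                n_test=len(x_test),
                f1=f1,
                precision=precision,
                recall=recall,
            )
        )
    return result


def synergy_test(per_fold_combined, per_fold_best_single) -> tuple[float, float]:
    """Paired t-test on fold-wise score differences (combined vs best single).

    Both vectors must come from identical fold assignments.  Returns (t, p),
    two-sided.
    """
    from scipy import stats as sps

    a = np.asarray(per_fold_combined, dtype=float)
    b = np.asarray(per_fold_best_single, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("fold-score vectors must be equal-length 1-D")
    d = a - b
    if d.std(ddof=1) == 0:
        return (0.0, 1.0) if d.mean() == 0 else (float(np.sign(d.mean()) * np.inf), 0.0)
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


def classification_report(
    table: pd.DataFrame,
    tasks=tuple(TASKS),
    k: int = 4,
    max_folds: int | None = None,
    seed: int | None = None,
    mean: str = "harmonic",
) -> dict:
    """Per-task scores: each single feature and the joint 12-feature model,
    with the synergy t-test of joint vs best single feature."""
    n_pianists = table["pianist_id"].nunique()
    if k >= n_pianists:
        k = n_pianists - 1
        log.info("clamping test-set size to %d (only %d pianists)", k, n_pianists)
    report: dict = {}
    for task in tasks:
        task_entry: dict = {"per_feature": {}, "k": k, "max_folds": max_folds, "seed": seed}
        single_results = {}
        for feat in FEATURE_NAMES:
            res = leave_k_pianists_out(
                table, task, k=k, features=feat, max_folds=max_folds, seed=seed, mean=mean
            )
            single_results[feat] = res
            task_entry["per_feature"][feat] = {"mean_f1": res.mean_f1, "sd_f1": res.sd_f1}
        combined = leave_k_pianists_out(
            table, task, k=k, features=tuple(FEATURE_NAMES), max_folds=max_folds, seed=seed, mean=mean
        )
        best_feat = max(single_results, key=lambda f: single_results[f].mean_f1)
        t, p = synergy_test(combined.fold_f1, single_results[best_feat].fold_f1)
        task_entry["combined"] = {"mean_f1": combined.mean_f1, "sd_f1": combined.sd_f1}
        task_entry["best_single"] = {
            "feature": best_feat,
            "mean_f1": single_results[best_feat].mean_f1,
        }
        task_entry["synergy"] = {"t": t, "p": p}
        report[task] = task_entry
    return report
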