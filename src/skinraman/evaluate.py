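"""Model evaluation: stratified K-fold cross-validation, latent-variable
selection, confusion-matrix metrics, ROC/AUC with vertical fold averaging,
Welch's t-test for cohort covariates, class mean/difference spectra, and a
harness comparing PCA-reduced reference classifiers.

Positive class throughout is eczema; sensitivity = tp / (tp + fn) is the
eczema detection rate, specificity = tn / (tn + fp) the healthy one.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.svm import SVC

from .chemometrics import PLSDAClassifier, SpectralPCA
from .dataset import SpectralDataset, ECZEMA
from .exceptions import ConfigError

__all__ = [
    "FoldAssignment",
    "ConfusionMatrix",
    "ErrorCurve",
    "CVReport",
    "stratified_kfold",
    "cm_metrics",
    "roc_curve",
    "auc",
    "mean_roc",
    "welch_ttest",
    "group_spectra",
    "select_num_lvs",
    "cross_validate_plsda",
    "reference_classifiers",
    "GaussianNaiveBayes",
    "KNearestNeighbors",
]


# --------------------------------------------------------------------------
# folds


@dataclass
class FoldAssignment:
    fold_ids: np.ndarray
    K: int
    seed: int

    def split(self):
        """Yield (train_idx, test_idx) per fold."""
        for k in range(self.K):
            test = np.flatnonzero(self.fold_ids == k)
            train = np.flatnonzero(self.fold_ids != k)
            yield train, test


def stratified_kfold(labels, K: int, seed: int) -> FoldAssignment:
    """Class-stratified folds: within each class, indices are shuffled and
    dealt round-robin to the K folds, so per-fold class counts differ from
    perfect proportionality by at most one. Deterministic given the seed.
    """
    if K < 2:
        raise ConfigError(f"K must be >= 2, got {K}")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    fold_ids = np.empty(labels.size, dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < K:
            warnings.warn(
                f"class {cls!r} has {idx.size} < K={K} samples; some folds lack it",
                stacklevel=2,
            )
        rng.shuffle(idx)
        fold_ids[idx] = np.arange(idx.size) % K
    return FoldAssignment(fold_ids, K, seed)


# --------------------------------------------------------------------------
# metrics


@dataclass
class ConfusionMatrix:
    tn: int = 0
    fp: int = 0
    fn: int = 0
    tp: int = 0

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ConfigError("confusion matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tn + other.tn, self.fp + other.fp, self.fn + other.fn, self.tp + other.tp
        )

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, bool)
        y_pred = np.asarray(y_pred, bool)
        return cls(
            tn=int(np.sum(~y_true & ~y_pred)),
            fp=int(np.sum(~y_true & y_pred)),
            fn=int(np.sum(y_true & ~y_pred)),
            tp=int(np.sum(y_true & y_pred)),
        )


def cm_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) at full precision."""
    if cm.total == 0:
        raise ConfigError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.total
    sensitivity = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else float("nan")
    specificity = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) > 0 else float("nan")
    return accuracy, sensitivity, specificity


def roc_curve(y_true, scores) -> np.ndarray:
    """ROC points as an (m, 2) array of (fpr, tpr), thresholds swept over
    the unique scores, anchored at (0, 0) and (1, 1)."""
    y_true = np.asarray(y_true, bool)
    if y_true.all() or not y_true.any():
        raise ConfigError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(y_true.astype(int), np.asarray(scores, float),
                                drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def auc(points: np.ndarray) -> float:
    """Trapezoid area under an (fpr, tpr) polyline; equals the pairwise
    statistic P(score+ > score-) + 0.5 P(score+ = score-)."""
    pts = np.asarray(points, float)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def mean_roc(curves: list[np.ndarray], n_grid: int = 101) -> np.ndarray:
    """Vertical averaging: TPR of each fold curve interpolated on a common
    FPR grid, then averaged across folds."""
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = np.vstack([np.interp(grid, c[:, 0], c[:, 1]) for c in curves])
    return np.column_stack([grid, tprs.mean(axis=0)])


def welch_ttest(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test: (t, df, two-sided p)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ConfigError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return float("inf"), float(a.size + b.size - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def group_spectra(dataset: SpectralDataset) -> dict:
    """Per-class mean and sample-SD spectra plus the eczema-minus-healthy
    difference spectrum."""
    out: dict = {"grid": dataset.grid}
    means = {}
    for cls in np.unique(dataset.labels):
        rows = dataset.X[dataset.labels == cls]
        if rows.shape[0] < 2:
            warnings.warn(f"class {cls!r} has < 2 subjects; SD reported as 0", stacklevel=2)
            sd = np.zeros(rows.shape[1])
        else:
            sd = rows.std(axis=0, ddof=1)
        means[cls] = rows.mean(axis=0)
        out[f"{cls}_mean"] = means[cls]
        out[f"{cls}_sd"] = sd
    if len(means) < 2:
        raise ConfigError("group_spectra needs both classes present")
    out["difference"] = means[ECZEMA] - means[[c for c in means if c != ECZEMA][0]]
    return out


# --------------------------------------------------------------------------
# latent-variable selection


@dataclass
class ErrorCurve:
    n_lvs: np.ndarray
    calibration_error: np.ndarray
    cv_error: np.ndarray
    chosen_A: int

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"n_lvs": self.n_lvs, "cal_error": self.calibration_error, "cv_error": self.cv_error}
        ).to_csv(path, index=False)


def select_num_lvs(
    dataset: SpectralDataset, A_max: int = 10, K: int = 10, seed: int = 0
) -> ErrorCurve:
    """Calibration and stratified K-fold CV misclassification rate for
    A = 1..A_max latent variables; ``chosen_A`` is the smallest A whose CV
    error matches the curve minimum (first-minimum rule).

    A single NIPALS run per fold provides all truncations, since the
    components are extracted greedily.
    """
    if A_max < 1:
        raise ConfigError("A_max must be >= 1")
    y = dataset.y()
    n = y.size
    A_eff = min(A_max, n - 1, dataset.X.shape[1])

    full = PLSDAClassifier(A_eff).fit(dataset.X, dataset.labels)
    cal = np.array(
        [
            np.mean(full.predict(dataset.X, n_components=min(A, full.n_components_)) != dataset.labels)
            for A in range(1, A_eff + 1)
        ]
    )

    folds = stratified_kfold(dataset.labels, K, seed)
    errors = np.zeros(A_eff)
    for train, test in folds.split():
        model = PLSDAClassifier(A_eff).fit(dataset.X[train], dataset.labels[train])
        for i, A in enumerate(range(1, A_eff + 1)):
            pred = model.predict(dataset.X[test], n_components=min(A, model.n_components_))
            errors[i] += np.sum(pred != dataset.labels[test])
    cv = errors / n

    chosen = int(np.flatnonzero(cv <= cv.min() + 1e-12)[0]) + 1
    return ErrorCurve(np.arange(1, A_eff + 1), cal, cv, chosen)


# --------------------------------------------------------------------------
# cross-validated evaluation


@dataclass
class CVReport:
    per_fold: list = field(default_factory=list)
    aggregated: ConfusionMatrix = field(default_factory=ConfusionMatrix)
    accuracy_mean: float = float("nan")
    accuracy_sd: float = float("nan")
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    auc_mean: float = float("nan")
    auc_sd: float = float("nan")
    mean_roc: np.ndarray | None = None
    n_components: int | None = None
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        obj = {
            "n_components": self.n_components,
            "seed": self.seed,
            "per_fold": [vars(cm) for cm in self.per_fold],
            "aggregated": vars(self.aggregated),
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
            "mean_roc": None if self.mean_roc is None else self.mean_roc.tolist(),
        }
        Path(path).write_text(json.dumps(obj, indent=2))


def _cv_with_scores(X, labels, scorer_factory, K, seed) -> CVReport:
    """Shared CV loop. ``scorer_factory(X_train, labels_train)`` returns a
    function mapping X_test to (continuous scores, boolean predictions)."""
    labels = np.asarray(labels)
    y_true_all = labels == ECZEMA
    folds = stratified_kfold(labels, K, seed)

    per_fold, accs, aucs, curves = [], [], [], []
    for train, test in folds.split():
        score_fn = scorer_factory(X[train], labels[train])
        scores, pred_pos = score_fn(X[test])
        y_true = y_true_all[test]
        cm = ConfusionMatrix.from_predictions(y_true, pred_pos)
        per_fold.append(cm)
        accs.append((cm.tp + cm.tn) / cm.total)
        if y_true.all() or not y_true.any():
            warnings.warn("fold with a single test class; AUC excluded", stacklevel=2)
        else:
            pts = roc_curve(y_true, scores)
            curves.append(pts)
            aucs.append(auc(pts))

    agg = sum(per_fold, ConfusionMatrix())
    accuracy, sensitivity, specificity = cm_metrics(agg)
    accs = np.asarray(accs)
    aucs = np.asarray(aucs)
    return CVReport(
        per_fold=per_fold,
        aggregated=agg,
        accuracy_mean=float(accs.mean()),
        accuracy_sd=float(accs.std(ddof=1)) if accs.size > 1 else 0.0,
        sensitivity=sensitivity,
        specificity=specificity,
        auc_mean=float(aucs.mean()) if aucs.size else float("nan"),
        auc_sd=float(aucs.std(ddof=1)) if aucs.size > 1 else float("nan"),
        mean_roc=mean_roc(list(curves)) if curves else None,
        seed=seed,
    )


def cross_validate_plsda(
    dataset: SpectralDataset, A: int, K: int = 10, seed: int = 0
) -> CVReport:
    """Stratified K-fold CV of the PLS-DA classifier with A components:
    per-fold confusion matrices and ROC curves, summed aggregate matrix,
    across-fold accuracy and AUC mean ± SD, vertically averaged mean ROC."""

    def factory(X_train, labels_train):
        model = PLSDAClassifier(A).fit(X_train, labels_train)

        def score(X_test):
            s = model.decision_function(X_test)
            return s, s >= model.threshold

        return score

    report = _cv_with_scores(dataset.X, dataset.labels, factory, K, seed)
    report.n_components = A
    return report


# --------------------------------------------------------------------------
# reference classifiers (PCA-reduced), native naive Bayes and KNN


class GaussianNaiveBayes:
    """Minimal Gaussian naive Bayes with per-class feature means/variances;
    score is the log posterior odds of the positive class."""

    def __init__(self, var_eps: float = 1e-9):
        self.var_eps = var_eps

    def fit(self, X, y_pos):
        X = np.asarray(X, float)
        y_pos = np.asarray(y_pos, bool)
        self.stats_ = {}
        for cls in (False, True):
            rows = X[y_pos == cls]
            self.stats_[cls] = (
                rows.mean(axis=0),
                rows.var(axis=0) + self.var_eps,
                np.log(rows.shape[0] / X.shape[0]),
            )
        return self

    def _loglik(self, X, cls):
        mu, var, logprior = self.stats_[cls]
        return logprior - 0.5 * np.sum(np.log(2 * np.pi * var) + (X - mu) ** 2 / var, axis=1)

    def score_samples(self, X):
        X = np.asarray(X, float)
        return self._loglik(X, True) - self._loglik(X, False)


class KNearestNeighbors:
    """Minimal Euclidean KNN; score is the fraction of positive labels
    among the k nearest training points."""

    def __init__(self, k: int = 4):
        self.k = k

    def fit(self, X, y_pos):
        self.X_ = np.asarray(X, float)
        self.y_ = np.asarray(y_pos, bool)
        return self

    def score_samples(self, X):
        X = np.asarray(X, float)
        d2 = ((X[:, None, :] - self.X_[None, :, :]) ** 2).sum(axis=2)
        k = min(self.k, self.X_.shape[0])
        nearest = np.argsort(d2, axis=1)[:, :k]
        return self.y_[nearest].mean(axis=1)


_REFERENCE_FACTORIES = {
    "lda": lambda: LinearDiscriminantAnalysis(),
    "logistic": lambda: LogisticRegression(max_iter=2000),
    "svm": lambda: SVC(kernel="linear"),
    "naive_bayes": lambda: GaussianNaiveBayes(),
    "knn": lambda: KNearestNeighbors(k=4),
}

#: classifier spec mirroring the reference comparison table
DEFAULT_REFERENCE_SPEC = [
    ("lda", 18),
    ("logistic", 14),
    ("naive_bayes", 6),
    ("knn", 17),
    ("svm", 11),
]


def reference_classifiers(
    dataset: SpectralDataset,
    spec: list[tuple[str, int]] | None = None,
    K: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """CV comparison of standard classifiers on PCA-reduced spectra.

    Each row applies PCA with the stated component count (fit on training
    folds only) followed by the named classifier, evaluated with the same
    stratified-CV machinery as the PLS-DA model.
    """
    spec = DEFAULT_REFERENCE_SPEC if spec is None else spec
    rows = []
    for name, n_pcs in spec:
        if name not in _REFERENCE_FACTORIES:
            raise ConfigError(f"unknown classifier {name!r}")

        def factory(X_train, labels_train, _name=name, _n=n_pcs):
            pca = SpectralPCA(_n).fit(X_train)
            Z = pca.transform(X_train)
            y_pos = np.asarray(labels_train) == ECZEMA
            clf = _REFERENCE_FACTORIES[_name]()
            if isinstance(clf, (GaussianNaiveBayes, KNearestNeighbors)):
                clf.fit(Z, y_pos)

                def score(X_test, _clf=clf, _pca=pca):
                    s = _clf.score_samples(_pca.transform(X_test))
                    return s, s >= (0.0 if isinstance(_clf, GaussianNaiveBayes) else 0.5)

            else:
                clf.fit(Z, y_pos.astype(int))

                def score(X_test, _clf=clf, _pca=pca):
                    Zt = _pca.transform(X_test)
                    if hasattr(_clf, "decision_function"):
                        s = _clf.decision_function(Zt)
                    else:
                        s = _clf.predict_proba(Zt)[:, 1]
                    return s, _clf.predict(Zt).astype(bool)

            return score

        rep = _cv_with_scores(dataset.X, dataset.labels, factory, K, seed)
        rows.append(
            {
                "classifier": name,
                "n_pcs": n_pcs,
                "accuracy_mean": rep.accuracy_mean,
                "accuracy_sd": rep.accuracy_sd,
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
                "auc_mean": rep.auc_mean,
                "auc_sd": rep.auc_sd,
            }
        )
    return pd.DataFrame(rows)
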