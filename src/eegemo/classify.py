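"""Classifiers, leave-one-subject-out evaluation and method comparison.

Cross-subject emotion recognition is evaluated with a leave-one-subject-out
(LOSO) strategy: each fold holds out every trial of one subject, fits the
whole pipeline — normalization, any feature selection, and the classifier —
on the remaining subjects only, and scores the held-out subject's trials.
The headline method is the ST-SBSSVM pipeline: a significance-test filter
followed by SVM-driven sequential backward selection, classified with an
RBF-kernel SVM.  Reference baselines (plain SVM, PCA-SVM, KNN, PCA-KNN,
random forest, and SBS without the filter stage) run on the same folds for
the comparison report.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GroupKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .datasets import DegenerateClassError
from .features import FeatureMatrix
from .selection import EmptySelectionError, sbs, significance_filter

__all__ = [
    "NormalizationModel",
    "fit_normalizer",
    "apply_normalizer",
    "train_svm_rbf",
    "baseline",
    "st_sbssvm",
    "BASELINE_METHODS",
    "EvaluationResult",
    "ComparisonReport",
    "loso_evaluate",
    "compare_methods",
]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationModel:
    """Per-column z-score parameters learned from training rows only."""

    center: np.ndarray
    scale: np.ndarray


def fit_normalizer(rows: np.ndarray) -> NormalizationModel:
    """Learn per-column center (mean) and scale (population std).

    Zero-variance columns get unit scale so they pass through centered
    (with a warning) rather than dividing by zero.
    """
    rows = np.asarray(rows, dtype=np.float64)
    if rows.shape[0] < 2:
        raise ValueError("fit_normalizer needs at least 2 rows")
    center = rows.mean(axis=0)
    scale = rows.std(axis=0)
    zero = scale == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance column(s); "
                      "centering only", stacklevel=2)
        scale = np.where(zero, 1.0, scale)
    return NormalizationModel(center=center, scale=scale)


def apply_normalizer(model: NormalizationModel, rows: np.ndarray) -> np.ndarray:
    return (np.asarray(rows, dtype=np.float64) - model.center) / model.scale


def train_svm_rbf(rows: np.ndarray, labels: np.ndarray, C: float = 1.0,
                  gamma: str | float = "scale") -> SVC:
    """Fit an RBF-kernel SVM on (already normalized) rows."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise DegenerateClassError("SVM training needs both classes")
    clf = SVC(C=C, kernel="rbf", gamma=gamma)
    clf.fit(rows, labels)
    return clf


# ---------------------------------------------------------------------------
# pipelines
# ---------------------------------------------------------------------------

class _NormalizedClassifier:
    """Z-score normalization + a sklearn classifier, fit per fold."""

    def __init__(self, name: str, make_estimator, pca_variance: float | None = None):
        self.name = name
        self._make = make_estimator
        self._pca_variance = pca_variance
        self.selected_features_: list[str] | None = None

    def fit(self, X, y, groups=None, column_names=None):
        self._norm = fit_normalizer(X)
        Z = apply_normalizer(self._norm, X)
        self._pca = None
        if self._pca_variance is not None:
            self._pca = PCA(n_components=self._pca_variance)
            Z = self._pca.fit_transform(Z)
        self._est = self._make()
        if len(np.unique(y)) < 2:
            raise DegenerateClassError("training fold has a single class")
        self._est.fit(Z, y)
        return self

    def predict(self, X):
        Z = apply_normalizer(self._norm, X)
        if self._pca is not None:
            Z = self._pca.transform(Z)
        return self._est.predict(Z)


class SBSSVMPipeline:
    """SVM-based sequential backward selection, optionally after the
    significance-test filter (the ST-SBSSVM configuration).

    Within each training fold, candidate feature subsets are scored by
    grouped k-fold cross-validation over the *training* subjects (so the
    held-out subject never influences selection), the best subset from the
    greedy backward trace is kept, and a final normalizer + RBF-SVM is fit
    on the full training fold restricted to that subset.
    """

    def __init__(self, st_filter: bool = True, alpha: float = 0.05,
                 test_choice: str = "auto", C: float = 1.0,
                 gamma: str | float = "scale", inner_splits: int = 5,
                 name: str | None = None):
        self.st_filter = st_filter
        self.alpha = alpha
        self.test_choice = test_choice
        self.C = C
        self.gamma = gamma
        self.inner_splits = inner_splits
        self.name = name or ("st_sbssvm" if st_filter else "sbs_svm")
        self.selected_features_: list[str] | None = None
        self.trace_: object | None = None
        self.filter_result_ = None

    def _subset_accuracy(self, X, y, groups, cols) -> float:
        Xc = X[:, cols]
        n_groups = len(np.unique(groups))
        n_splits = min(self.inner_splits, n_groups)
        if n_splits < 2:
            # single training subject: score on the training rows themselves
            norm = fit_normalizer(Xc)
            clf = train_svm_rbf(apply_normalizer(norm, Xc), y, self.C,
                                self.gamma)
            return float((clf.predict(apply_normalizer(norm, Xc)) == y).mean())
        accs = []
        for tr, va in GroupKFold(n_splits=n_splits).split(Xc, y, groups):
            if len(np.unique(y[tr])) < 2:
                continue
            norm = fit_normalizer(Xc[tr])
            clf = train_svm_rbf(apply_normalizer(norm, Xc[tr]), y[tr],
                                self.C, self.gamma)
            pred = clf.predict(apply_normalizer(norm, Xc[va]))
            accs.append(float((pred == y[va]).mean()))
        return float(np.mean(accs)) if accs else 0.0

    def fit(self, X, y, groups=None, column_names=None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if groups is None:
            groups = np.zeros(len(y), dtype=int)
        names = (list(column_names) if column_names is not None
                 else [f"col{i}" for i in range(X.shape[1])])
        cols = np.arange(X.shape[1])
        self.filter_result_ = None
        if self.st_filter:
            try:
                res = significance_filter(X, y, alpha=self.alpha,
                                          test_choice=self.test_choice)
                cols = np.flatnonzero(res.retained_mask)
                self.filter_result_ = res
            except EmptySelectionError:
                warnings.warn("significance filter retained no columns; "
                              "falling back to the full feature set",
                              stacklevel=2)
        kept_names = [names[i] for i in cols]
        if len(cols) >= 2:
            trace = sbs(kept_names,
                        lambda subset: self._subset_accuracy(
                            X, y, groups, cols[np.asarray(subset, dtype=int)]))
            self.trace_ = trace
            name_to_idx = {names[i]: i for i in cols}
            sel = np.array([name_to_idx[n] for n in trace.best_subset])
        else:
            self.trace_ = None
            sel = cols
        self.selected_idx_ = sel
        self.selected_features_ = [names[i] for i in sel]
        self._norm = fit_normalizer(X[:, sel])
        self._clf = train_svm_rbf(apply_normalizer(self._norm, X[:, sel]), y,
                                  self.C, self.gamma)
        return self

    def predict(self, X):
        Xs = np.asarray(X, dtype=np.float64)[:, self.selected_idx_]
        return self._clf.predict(apply_normalizer(self._norm, Xs))


BASELINE_METHODS = ("svm", "pca_svm", "knn", "pca_knn", "rf", "sbs_svm")


def baseline(method: str, C: float = 1.0, gamma: str | float = "scale",
             k: int = 5, n_trees: int = 100, pca_variance: float = 0.95,
             random_state: int = 0):
    """Construct one of the reference pipelines run on the full
    (unselected) high-dimensional feature matrix."""
    if method == "svm":
        return _NormalizedClassifier("svm", lambda: SVC(C=C, kernel="rbf",
                                                        gamma=gamma))
    if method == "pca_svm":
        return _NormalizedClassifier("pca_svm",
                                     lambda: SVC(C=C, kernel="rbf", gamma=gamma),
                                     pca_variance=pca_variance)
    if method == "knn":
        return _NormalizedClassifier("knn",
                                     lambda: KNeighborsClassifier(n_neighbors=k))
    if method == "pca_knn":
        return _NormalizedClassifier("pca_knn",
                                     lambda: KNeighborsClassifier(n_neighbors=k),
                                     pca_variance=pca_variance)
    if method == "rf":
        return _NormalizedClassifier(
            "rf", lambda: RandomForestClassifier(n_estimators=n_trees,
                                                 random_state=random_state))
    if method == "sbs_svm":
        return SBSSVMPipeline(st_filter=False, C=C, gamma=gamma,
                              name="sbs_svm")
    raise ValueError(f"unknown baseline method {method!r}; "
                     f"choose from {BASELINE_METHODS}")


def st_sbssvm(alpha: float = 0.05, test_choice: str = "auto", C: float = 1.0,
              gamma: str | float = "scale",
              inner_splits: int = 5) -> SBSSVMPipeline:
    """The headline pipeline: significance-test filter + SBS + RBF-SVM."""
    return SBSSVMPipeline(st_filter=True, alpha=alpha,
                          test_choice=test_choice, C=C, gamma=gamma,
                          inner_splits=inner_splits)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    """LOSO outcome: one accuracy per held-out subject."""

    fold_subjects: list
    fold_accuracies: list[float]
    fold_selected: list[list[str] | None]
    wall_seconds: float
    method: str = ""

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"method": self.method,
             "fold_subjects": [str(s) for s in self.fold_subjects],
             "fold_accuracies": self.fold_accuracies,
             "mean_accuracy": self.mean_accuracy,
             "fold_selected": self.fold_selected}, indent=2))
        # wall_seconds is kept off the report so identical reruns are
        # byte-identical; runtimes go to the log instead


def loso_evaluate(fm: FeatureMatrix, pipeline) -> EvaluationResult:
    """Leave-one-subject-out evaluation of a pipeline.

    One fold per distinct subject: the pipeline is re-fit on all other
    subjects' rows (selection and normalization included) and scored as
    the fraction of the held-out subject's trials classified correctly.
    """
    subjects = np.unique(fm.subject_id)
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 distinct subjects")
    fold_subjects, fold_accs, fold_sel = [], [], []
    t0 = time.perf_counter()
    for subj in subjects:
        test = fm.subject_id == subj
        train = ~test
        if not test.any():
            warnings.warn(f"subject {subj!r} has no trials; fold skipped",
                          stacklevel=2)
            continue
        pipeline.fit(fm.values[train], fm.labels[train],
                     groups=fm.subject_id[train],
                     column_names=fm.column_names)
        pred = pipeline.predict(fm.values[test])
        fold_subjects.append(subj)
        fold_accs.append(float((pred == fm.labels[test]).mean()))
        fold_sel.append(getattr(pipeline, "selected_features_", None))
    return EvaluationResult(fold_subjects=fold_subjects,
                            fold_accuracies=fold_accs,
                            fold_selected=fold_sel,
                            wall_seconds=time.perf_counter() - t0,
                            method=getattr(pipeline, "name", ""))


# ---------------------------------------------------------------------------
# comparison report
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Per-method LOSO accuracies and differences from the reference.

    ``differences_pct[m]`` = (reference accuracy − method accuracy) in
    percentage points; ``average_difference_pct`` is their arithmetic mean.
    """

    reference: str
    accuracies: dict = field(default_factory=dict)      # fractions in [0,1]
    differences_pct: dict = field(default_factory=dict)
    evaluations: dict = field(default_factory=dict)

    @property
    def average_difference_pct(self) -> float:
        return float(np.mean(list(self.differences_pct.values())))

    @classmethod
    def from_accuracies(cls, reference: str,
                        accuracies: Mapping[str, float]) -> "ComparisonReport":
        """Build a report from externally supplied accuracies (fractions)."""
        ref_acc = accuracies[reference]
        diffs = {m: (ref_acc - a) * 100.0 for m, a in accuracies.items()
                 if m != reference}
        return cls(reference=reference, accuracies=dict(accuracies),
                   differences_pct=diffs)

    @classmethod
    def from_differences(cls, reference: str,
                         differences_pct: Mapping[str, float]
                         ) -> "ComparisonReport":
        """Build a report directly from printed percentage-point differences."""
        return cls(reference=reference,
                   differences_pct=dict(differences_pct))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"reference": self.reference,
             "accuracies": {m: float(a) for m, a in self.accuracies.items()},
             "differences_pct": {m: float(d)
                                 for m, d in self.differences_pct.items()},
             "average_difference_pct": self.average_difference_pct},
            indent=2))


def compare_methods(fm: FeatureMatrix,
                    methods: Sequence[str] = BASELINE_METHODS,
                    reference=None, random_state: int = 0) -> ComparisonReport:
    """Run the reference pipeline and every baseline on identical LOSO
    folds and report percentage-point differences from the reference."""
    ref = reference if reference is not None else st_sbssvm()
    ref_eval = loso_evaluate(fm, ref)
    report = ComparisonReport(reference=getattr(ref, "name", "st_sbssvm"))
    report.accuracies[report.reference] = ref_eval.mean_accuracy
    report.evaluations[report.reference] = ref_eval
    for method in methods:
        ev = loso_evaluate(fm, baseline(method, random_state=random_state))
        if ev.fold_subjects != ref_eval.fold_subjects:
            raise ValueError(f"fold mismatch between {method} and reference")
        report.accuracies[method] = ev.mean_accuracy
        report.differences_pct[method] = (
            ref_eval.mean_accuracy - ev.mean_accuracy) * 100.0
        report.evaluations[method] = ev
    return report
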